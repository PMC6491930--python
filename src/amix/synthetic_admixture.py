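"""Forward-in-time simulator of admixed populations with assortative mating.

The generator produces diploid individuals carrying per-gene haplotype
ancestry labels from {AFR, EUR, NAT}, the exact data structure the AMI
pipeline consumes, together with truth records for validation.

Model
-----
Founders are diploids homozygous for a single ancestry at every gene, drawn
according to the founder mixture proportions — an instantaneous admixture
event.  A burn-in of random-mating generations first creates the admixed
standing variation that the AMI presupposes (mate choice in a population
where everyone is a single-ancestry founder line cannot produce admixed
genomes at all: similar-ancestry pairing simply perpetuates the lines).
After burn-in, each discrete generation of the configured mating model:

1. Every individual's ancestry profile is computed: the per-gene ancestry
   dosage (count of each ancestry among the two gene copies, halved),
   restricted to the designated trait genes when assortment is
   trait-restricted, or to a single ancestry's dosage in
   ancestry-component mode.  Mate similarity on realized local ancestry,
   gene by gene, is the mechanism that yields locus-level ancestry
   homozygosity in offspring; similarity on genome-averaged fractions
   alone couples far too weakly to individual loci.
2. Monogamous mate pairs are formed by sequential weighted sampling without
   replacement: a focal individual is drawn uniformly, and its mate drawn
   from the remaining pool with weight exp(-strength * d), where d is the
   Euclidean distance between the two dosage profiles, normalized by the
   square root of the number of profiled genes (so d is in [0, sqrt(2)]
   regardless of the gene count).  Strength 0 is random mating;
   self-mating is impossible by construction.
3. Each pair produces enough offspring to keep the population size constant
   (sizes not divisible by the pair count are balanced by giving some pairs
   one extra child).  Each offspring gene-haplotype is copied uniformly from
   the parent's two gene copies, independently across genes — free
   recombination, i.e. genes are unlinked.

Assortative mating under this model changes genotype frequencies (excess
ancestry homozygosity) but not expected ancestry proportions, which is the
signal regime the AMI is designed for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .ancestry_io import ANCESTRIES, ANCESTRY_CODE, AncestryGenotypeMatrix, \
    AncestrySegment, GeneAnnotation, write_ancestry_segments as _write_segments, \
    write_gene_annotations
from .gene_sets import GeneSet, write_gene_sets

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class SimulationConfig:
    """Parameters of one simulated admixed population.

    assortment_strength is the decay rate of the mate-pair weight
    exp(-strength * d); 0 means random mating, and values around 5-10 give
    strong assortment on the 0-1 scale of ancestry-fraction distances.
    """

    n_individuals: int = 200
    n_genes: int = 500
    n_generations: int = 10
    n_burnin_generations: int = 5
    founder_proportions: tuple[float, float, float] = (0.2, 0.5, 0.3)
    assortment_strength: float = 0.0
    assort_on: str = "global_ancestry"  # or "gene_subset" or "ancestry_component"
    trait_genes: tuple[str, ...] | None = None
    assort_ancestry: str | None = None  # for assort_on="ancestry_component"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need >= 2 individuals")
        if self.n_genes < 1 or self.n_generations < 0:
            raise ValueError("n_genes >= 1 and n_generations >= 0 required")
        if self.n_burnin_generations < 0:
            raise ValueError("n_burnin_generations must be >= 0")
        props = np.asarray(self.founder_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"founder proportions {props} must sum to 1")
        if self.assortment_strength < 0:
            raise ValueError("assortment_strength must be >= 0")
        if self.assort_on not in ("global_ancestry", "gene_subset",
                                  "ancestry_component"):
            raise ValueError(f"unknown assort_on {self.assort_on!r}")
        if self.assort_on == "gene_subset" and not self.trait_genes:
            raise ValueError("assort_on='gene_subset' requires trait_genes")
        if self.assort_on == "ancestry_component":
            if self.assort_ancestry not in ANCESTRY_CODE:
                raise ValueError(
                    "assort_on='ancestry_component' requires assort_ancestry "
                    f"in {ANCESTRIES}"
                )

    def as_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_genes": self.n_genes,
            "n_generations": self.n_generations,
            "n_burnin_generations": self.n_burnin_generations,
            "founder_proportions": list(self.founder_proportions),
            "assortment_strength": self.assortment_strength,
            "assort_on": self.assort_on,
            "trait_genes": list(self.trait_genes) if self.trait_genes else None,
            "assort_ancestry": self.assort_ancestry,
            "seed": self.seed,
        }


@dataclass(slots=True)
class SimTruth:
    """Simulator ground truth emitted alongside the data."""

    config: SimulationConfig
    global_fractions: np.ndarray  # (N, 3) final-generation per-individual
    mate_correlation: list[float]  # per generation, mean over ancestry components


def _gene_ids(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _global_fractions(haps: np.ndarray) -> np.ndarray:
    """Per-individual (N, 3) global ancestry fractions."""
    n = haps.shape[0]
    flat = haps.reshape(n, -1)
    return np.stack([(flat == k).mean(axis=1) for k in range(3)], axis=1)


def _dosage_profiles(
    haps: np.ndarray, gene_idx: np.ndarray | None, component: int | None
) -> np.ndarray:
    """Per-individual ancestry-dosage profiles used for mate matching.

    haps: (N, G, 2) int8 codes.  Returns (N, F) with the per-gene dosage of
    each ancestry (halved, so each entry is 0, 0.5 or 1), restricted to
    ``gene_idx`` columns, and scaled by 1/sqrt(#genes) so Euclidean row
    distances live on a fixed [0, sqrt(2)] scale whatever the gene count.

    In ancestry-component mode (``component`` given) the profile collapses
    to the scalar genome fraction of that ancestry: assortment then acts on
    the ancestry *proportion*, the trait-like quantity whose inter-individual
    variance assortative mating classically inflates.  Distances on this
    scalar are roughly an order of magnitude smaller than profile distances,
    so comparable assortment requires correspondingly larger strength.
    """
    sub = haps if gene_idx is None else haps[:, gene_idx, :]
    n, g, _ = sub.shape
    if component is not None:
        return (sub.reshape(n, -1) == component).mean(axis=1)[:, None]
    dos = np.stack([(sub == k).sum(axis=2) for k in range(3)], axis=2) / 2.0
    return dos.reshape(n, -1) / np.sqrt(g)


def _form_pairs(
    vecs: np.ndarray, strength: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Sequential weighted monogamous pairing without replacement."""
    n = vecs.shape[0]
    unpaired = list(range(n))
    pairs: list[tuple[int, int]] = []
    while len(unpaired) >= 2:
        i = unpaired.pop(rng.integers(len(unpaired)))
        rest = np.asarray(unpaired)
        if strength == 0.0:
            j_idx = rng.integers(len(unpaired))
        else:
            d = np.linalg.norm(vecs[rest] - vecs[i], axis=1)
            w = np.exp(-strength * d)
            w_sum = w.sum()
            if w_sum <= 0:  # extreme strength: fall back to nearest
                j_idx = int(np.argmin(d))
            else:
                j_idx = rng.choice(len(unpaired), p=w / w_sum)
        j = unpaired.pop(j_idx)
        pairs.append((i, j))
    return pairs


def _pair_correlation(vecs: np.ndarray, pairs: Sequence[tuple[int, int]]) -> float:
    """Mean Pearson correlation of mates' ancestry fractions, over components
    with non-degenerate variance; NaN if every component is degenerate."""
    lefts = np.array([p[0] for p in pairs])
    rights = np.array([p[1] for p in pairs])
    rs = []
    for k in range(vecs.shape[1]):
        x, y = vecs[lefts, k], vecs[rights, k]
        # symmetrize: a pair's ordering is arbitrary
        x2 = np.concatenate([x, y])
        y2 = np.concatenate([y, x])
        if x2.std() == 0:
            continue
        rs.append(float(np.corrcoef(x2, y2)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


def simulate_admixed_population(
    cfg: SimulationConfig,
    population_id: str = "sim",
) -> tuple[AncestryGenotypeMatrix, SimTruth]:
    """Run the forward simulation and emit the final generation.

    Deterministic under ``cfg.seed``.  With ``n_generations == 0`` the
    founders themselves are returned.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg.n_genes)
    n, g = cfg.n_individuals, cfg.n_genes

    gene_idx: np.ndarray | None = None
    if cfg.assort_on == "gene_subset":
        id_to_idx = {gid: i for i, gid in enumerate(gene_ids)}
        missing = [t for t in cfg.trait_genes if t not in id_to_idx]
        if missing:
            raise ValueError(f"trait genes not in gene universe: {missing}")
        gene_idx = np.asarray([id_to_idx[t] for t in cfg.trait_genes])
    component = (
        ANCESTRY_CODE[cfg.assort_ancestry]
        if cfg.assort_on == "ancestry_component"
        else None
    )

    # founders: homozygous one-ancestry diploids
    founder_anc = rng.choice(3, size=n, p=np.asarray(cfg.founder_proportions))
    haps = np.broadcast_to(
        founder_anc[:, None, None], (n, g, 2)
    ).astype(np.int8).copy()

    mate_corr: list[float] = []
    total_gens = cfg.n_burnin_generations + cfg.n_generations
    for gen in range(total_gens):
        burnin = gen < cfg.n_burnin_generations
        strength = 0.0 if burnin else cfg.assortment_strength
        profiles = _dosage_profiles(haps, gene_idx, component)
        pairs = _form_pairs(profiles, strength, rng)
        if not burnin:
            mate_corr.append(_pair_correlation(_global_fractions(haps), pairs))
        # offspring allocation: keep population size constant
        n_pairs = len(pairs)
        counts = np.full(n_pairs, n // n_pairs, dtype=int)
        extra = rng.permutation(n_pairs)[: n % n_pairs]
        counts[extra] += 1
        mothers = np.repeat([p[0] for p in pairs], counts)
        fathers = np.repeat([p[1] for p in pairs], counts)
        gcols = np.arange(g)
        picks_m = rng.integers(2, size=(n, g))
        picks_f = rng.integers(2, size=(n, g))
        child = np.empty((n, g, 2), dtype=np.int8)
        child[:, :, 0] = haps[mothers[:, None], gcols[None, :], picks_m]
        child[:, :, 1] = haps[fathers[:, None], gcols[None, :], picks_f]
        haps = child

    width = len(str(n))
    individuals = [f"ind{i + 1:0{width}d}" for i in range(n)]
    matrix = AncestryGenotypeMatrix(
        population_id=population_id,
        genes=gene_ids,
        individuals=individuals,
        haps=np.transpose(haps, (1, 0, 2)),  # -> (G, N, 2)
    )
    truth = SimTruth(
        config=cfg,
        global_fractions=_global_fractions(haps),
        mate_correlation=mate_corr,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# emitting pipeline-consumable files
# ---------------------------------------------------------------------------


def default_gene_annotations(
    gene_ids: Sequence[str], n_chroms: int = 22
) -> list[GeneAnnotation]:
    """Lay simulated genes out on autosomes: 100 kb genes, 200 kb apart."""
    genes = []
    per_chrom: dict[int, int] = {}
    for i, gid in enumerate(gene_ids):
        c = i % n_chroms
        j = per_chrom.get(c, 0)
        per_chrom[c] = j + 1
        start = 1_000_000 + j * 200_000
        genes.append(GeneAnnotation(gid, f"chr{c + 1}", start, start + 100_000))
    return genes


def matrix_to_segments(
    matrix: AncestryGenotypeMatrix,
    genes: Sequence[GeneAnnotation],
    certainty: float = 1.0,
) -> list[AncestrySegment]:
    """One segment per assigned gene-haplotype, spanning the gene exactly."""
    by_id = {g.gene_id: g for g in genes}
    segments: list[AncestrySegment] = []
    for gi, gid in enumerate(matrix.genes):
        ann = by_id[gid]
        for ni, ind in enumerate(matrix.individuals):
            for hap in (0, 1):
                code = matrix.haps[gi, ni, hap]
                if code < 0:
                    continue
                segments.append(
                    AncestrySegment(ind, hap, ann.chrom, ann.start, ann.end,
                                    ANCESTRIES[code], certainty)
                )
    return segments


def write_ancestry_segments(
    matrix: AncestryGenotypeMatrix,
    genes: Sequence[GeneAnnotation],
    path: str | Path,
    certainty: float = 1.0,
) -> None:
    """Serialize a genotype matrix as a segment TSV (certainty 1.0 for
    simulated data); round-trips through genotype calling on the same genes."""
    _write_segments(matrix_to_segments(matrix, genes, certainty), path)


def generate_fixture_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_individuals: int = 200,
    n_genes: int = 300,
    n_generations: int = 10,
    trait_strength: float = 10.0,
) -> dict[str, object]:
    """Write a small self-consistent multi-population dataset.

    Four synthetic populations echo qualitatively distinct admixture
    profiles (one European-heavy three-way mix, one Native-American-heavy,
    one with substantial African ancestry, one strongly European).  One
    population ("popB") mates assortatively restricted to the trait gene
    set ``trait_assort`` with the given strength; the others mate randomly.
    Emits per-population segment TSVs, a gene BED, a GMT of ~10 sets
    (sizes 2-30), an LD table, and a YAML run config.  Byte-identical under
    one seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    gene_ids = _gene_ids(n_genes)
    genes = default_gene_annotations(gene_ids)
    write_gene_annotations(genes, outdir / "genes.bed")

    profiles = {
        "popA": (0.10, 0.65, 0.25),   # European-heavy three-way
        "popB": (0.05, 0.45, 0.50),   # Native-American-heavy
        "popC": (0.30, 0.55, 0.15),   # substantial African ancestry
        "popD": (0.12, 0.73, 0.15),   # strongly European
    }
    trait_genes = tuple(
        sorted(rng.choice(gene_ids, size=30, replace=False).tolist())
    )

    set_sizes = [2, 4, 6, 8, 10, 12, 15, 20, 30]
    categories = ["anthropometric", "neurological", "HLA", "other"]
    sets = [GeneSet("trait_assort", "anthropometric", trait_genes)]
    for i, size in enumerate(set_sizes):
        members = tuple(
            sorted(rng.choice(gene_ids, size=size, replace=False).tolist())
        )
        sets.append(GeneSet(f"null_set_{i + 1:02d}", categories[i % 4], members))
    write_gene_sets(sets, outdir / "gene_sets.gmt")

    # a few LD'd pairs inside the larger sets, plus benign pairs
    ld_lines = []
    big = sets[-1].gene_ids
    ld_lines.append((big[0], big[1], 0.45))
    ld_lines.append((big[2], big[3], 0.15))
    ld_lines.append((sets[5].gene_ids[0], sets[5].gene_ids[1], 0.30))
    ld_lines.append((gene_ids[0], gene_ids[1], 0.05))
    with open(outdir / "ld.tsv", "w") as fh:
        fh.write("#gene_a\tgene_b\tr2\n")
        for a, b, r2 in ld_lines:
            fh.write(f"{a}\t{b}\t{r2:.2f}\n")

    pop_paths = {}
    for pi, (pop, props) in enumerate(profiles.items()):
        assorted = pop == "popB"
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_genes=n_genes,
            n_generations=n_generations,
            founder_proportions=props,
            assortment_strength=trait_strength if assorted else 0.0,
            assort_on="gene_subset" if assorted else "global_ancestry",
            trait_genes=trait_genes if assorted else None,
            seed=int(rng.integers(2**31)),
        )
        matrix, _ = simulate_admixed_population(cfg, population_id=pop)
        seg_path = outdir / f"{pop}.segments.tsv"
        write_ancestry_segments(matrix, genes, seg_path)
        pop_paths[pop] = seg_path.name

    config = {
        "populations": pop_paths,
        "genes_bed": "genes.bed",
        "gene_sets_gmt": "gene_sets.gmt",
        "ld_table": "ld.tsv",
        "min_certainty": 0.99,
        "r2_max": 0.1,
        "min_set_size": 2,
        "n_virtual_diploids": 10_000,
        "n_gene_set_perms": 1_000,
        "seed": seed,
        "output_dir": "results",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {"config": config, "trait_genes": trait_genes, "profiles": profiles}
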