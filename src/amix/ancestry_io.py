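"""Reading, writing, and genotype-calling of local-ancestry segments.

Local ancestry assigns each haplotype segment of an admixed genome to one of
three continental source populations: African (``AFR``), European (``EUR``)
or Native American (``NAT``).  This module parses segment calls (either a
simple per-segment TSV dialect or RFMix-v1 Viterbi output), parses gene
annotations from BED, and calls a per-gene *ancestry genotype* for every
diploid individual: an unordered pair of ancestry labels when both haplotypes
are confidently assigned over the gene, a single label when only one is, or
missing.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical ancestry labels, in fixed code order (code = index).
ANCESTRIES: tuple[str, str, str] = ("AFR", "EUR", "NAT")
ANCESTRY_CODE: dict[str, int] = {a: i for i, a in enumerate(ANCESTRIES)}
MISSING: int = -1

#: Chromosomes excluded from analysis (autosomes only).
_NON_AUTOSOMAL = {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}


class ParseError(ValueError):
    """A malformed input line; message carries the file and line number."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True, slots=True)
class AncestrySegment:
    """One contiguous local-ancestry call on a single haplotype."""

    individual_id: str
    haplotype_index: int  # 0 or 1
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    ancestry: str  # one of ANCESTRIES
    certainty: float = 1.0

    def __post_init__(self) -> None:
        if self.haplotype_index not in (0, 1):
            raise ValidationError(
                f"haplotype_index must be 0 or 1, got {self.haplotype_index}"
            )
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"bad interval [{self.start}, {self.end}) for {self.individual_id}"
            )
        if self.ancestry not in ANCESTRY_CODE:
            raise ParseError(f"unknown ancestry label {self.ancestry!r}")
        if not 0.0 <= self.certainty <= 1.0:
            raise ValidationError(f"certainty {self.certainty} outside [0, 1]")


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """A gene interval; 0-based half-open, as in BED."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} <= start {self.start}"
            )


@dataclass
class AncestryGenotypeMatrix:
    """Per-population grid of per-gene ancestry genotypes.

    ``haps`` has shape (n_genes, n_individuals, 2) with ancestry codes
    (0=AFR, 1=EUR, 2=NAT) or -1 for an unassigned haplotype.  Pairs are
    stored sorted so the genotype is unordered; a single assignment is
    stored as (code, -1); missing is (-1, -1).
    """

    population_id: str
    genes: list[str]
    individuals: list[str]
    haps: np.ndarray  # int8, (G, N, 2)

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.shape != (len(self.genes), len(self.individuals), 2):
            raise ValidationError(
                f"haps shape {self.haps.shape} does not match "
                f"{len(self.genes)} genes x {len(self.individuals)} individuals"
            )
        # normalize: sort pair descending-missing-last -> put -1 second
        self.haps = np.sort(self.haps, axis=2)[:, :, ::-1]
        # after descending sort a full pair is (hi, lo); re-sort full pairs asc
        full = self.haps[:, :, 1] >= 0
        lo = np.where(full, self.haps[:, :, 1], self.haps[:, :, 0])
        hi = np.where(full, self.haps[:, :, 0], self.haps[:, :, 1])
        self.haps = np.stack([lo, hi], axis=2).astype(np.int8)

    @property
    def full_pair_mask(self) -> np.ndarray:
        """(G, N) boolean: both haplotypes assigned."""
        return (self.haps >= 0).all(axis=2)

    @property
    def n_pairs(self) -> np.ndarray:
        """Per-gene count of individuals with a full ancestry pair."""
        return self.full_pair_mask.sum(axis=1)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.genes.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def subset_genes(self, keep: Sequence[int]) -> "AncestryGenotypeMatrix":
        keep = list(keep)
        return AncestryGenotypeMatrix(
            population_id=self.population_id,
            genes=[self.genes[i] for i in keep],
            individuals=list(self.individuals),
            haps=self.haps[keep].copy(),
        )

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write genes x individuals TSV with cells 'AFR/EUR', 'EUR' or '.'."""
        with open(path, "w") as fh:
            fh.write("#population=%s\n" % self.population_id)
            fh.write("gene_id\t" + "\t".join(self.individuals) + "\n")
            for gi, gid in enumerate(self.genes):
                cells = []
                for ni in range(len(self.individuals)):
                    a, b = self.haps[gi, ni]
                    if a < 0 and b < 0:
                        cells.append(".")
                    elif b < 0:
                        cells.append(ANCESTRIES[a])
                    else:
                        cells.append(f"{ANCESTRIES[a]}/{ANCESTRIES[b]}")
                fh.write(gid + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AncestryGenotypeMatrix":
        path = Path(path)
        population_id = path.stem
        genes: list[str] = []
        rows: list[list[tuple[int, int]]] = []
        individuals: list[str] | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#population="):
                        population_id = line.split("=", 1)[1]
                    continue
                fields = line.split("\t")
                if individuals is None:
                    individuals = fields[1:]
                    continue
                genes.append(fields[0])
                row = []
                for cell in fields[1:]:
                    if cell == ".":
                        row.append((MISSING, MISSING))
                    elif "/" in cell:
                        x, y = cell.split("/")
                        row.append((ANCESTRY_CODE[x], ANCESTRY_CODE[y]))
                    else:
                        row.append((ANCESTRY_CODE[cell], MISSING))
                rows.append(row)
        if individuals is None:
            raise ParseError(f"{path}: no header line found")
        haps = np.array(rows, dtype=np.int8).reshape(len(genes), len(individuals), 2)
        return cls(population_id, genes, individuals, haps)


# ---------------------------------------------------------------------------
# segment I/O
# ---------------------------------------------------------------------------


def _check_no_overlap(segments: Iterable[AncestrySegment]) -> None:
    by_hap: dict[tuple[str, int, str], list[AncestrySegment]] = {}
    for s in segments:
        by_hap.setdefault((s.individual_id, s.haplotype_index, s.chrom), []).append(s)
    for key, segs in by_hap.items():
        segs.sort(key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"overlapping segments on {key}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def read_ancestry_segments(
    path: str | Path,
    dialect: str = "segment_tsv",
    *,
    positions_path: str | Path | None = None,
    sample_ids: Sequence[str] | None = None,
    code_map: dict[int, str] | None = None,
) -> list[AncestrySegment]:
    """Read local-ancestry segments.

    Parameters
    ----------
    path
        Segment file.  For ``segment_tsv``: whitespace-separated columns
        (individual, haplotype, chrom, start, end, ancestry, certainty),
        ``#`` comment lines ignored.  For ``rfmix_v1``: a Viterbi matrix
        (rows = markers, columns = haplotypes, integer ancestry codes).
    dialect
        ``"segment_tsv"`` or ``"rfmix_v1"``.
    positions_path
        Required for ``rfmix_v1``: one physical marker position (1-based bp)
        per line, same order as the Viterbi rows.
    sample_ids
        For ``rfmix_v1``: individual ids for consecutive haplotype-column
        pairs; defaults to ``ind1..indN``.
    code_map
        For ``rfmix_v1``: mapping of integer codes to ancestry labels
        (default ``{1: AFR, 2: EUR, 3: NAT}``).

    Raising certainty thresholds is deferred to genotype calling; the reader
    preserves certainty values as given (``rfmix_v1`` Viterbi calls carry no
    per-segment posterior, so certainty defaults to 1.0 there).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "segment_tsv":
        segments = _read_segment_tsv(path)
    elif dialect == "rfmix_v1":
        if positions_path is None:
            raise ValueError("rfmix_v1 dialect requires a marker positions_path")
        segments = _read_rfmix_v1(path, positions_path, sample_ids, code_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_no_overlap(segments)
    if not segments:
        logger.warning("no segments read from %s", path)
    return segments


def _read_segment_tsv(path: Path) -> list[AncestrySegment]:
    segments: list[AncestrySegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            ind, hap, chrom, start, end, anc, cert = fields
            try:
                seg = AncestrySegment(
                    individual_id=ind,
                    haplotype_index=int(hap),
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    ancestry=anc,
                    certainty=float(cert),
                )
            except (ValueError, ValidationError, ParseError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            segments.append(seg)
    return segments


def _read_rfmix_v1(
    path: Path,
    positions_path: str | Path,
    sample_ids: Sequence[str] | None,
    code_map: dict[int, str] | None,
) -> list[AncestrySegment]:
    """Collapse a marker-by-haplotype Viterbi matrix into run segments.

    A run of markers i..j with one code becomes the 0-based half-open
    interval [pos_i - 1, pos_j) (positions are 1-based physical bp).
    All markers are taken to lie on one chromosome, named 'chr1' unless a
    '#chrom=' header is present in the positions file.
    """
    if code_map is None:
        code_map = {1: "AFR", 2: "EUR", 3: "NAT"}
    chrom = "chr1"
    positions: list[int] = []
    with open(positions_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#chrom="):
                    chrom = line.split("=", 1)[1]
                continue
            positions.append(int(float(line)))
    calls = np.loadtxt(path, dtype=int, ndmin=2)
    if calls.shape[0] != len(positions):
        raise ValidationError(
            f"{path}: {calls.shape[0]} marker rows but "
            f"{len(positions)} positions supplied"
        )
    n_haps = calls.shape[1]
    if n_haps % 2:
        raise ValidationError(f"{path}: odd haplotype column count {n_haps}")
    if sample_ids is None:
        sample_ids = [f"ind{i + 1}" for i in range(n_haps // 2)]
    elif len(sample_ids) != n_haps // 2:
        raise ValidationError(
            f"{len(sample_ids)} sample ids for {n_haps // 2} individuals"
        )
    segments: list[AncestrySegment] = []
    for col in range(n_haps):
        ind = sample_ids[col // 2]
        hap = col % 2
        run_start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or calls[i, col] != calls[run_start, col]:
                code = int(calls[run_start, col])
                if code not in code_map:
                    raise ParseError(
                        f"{path}: unknown ancestry code {code} in column {col}"
                    )
                segments.append(
                    AncestrySegment(
                        individual_id=ind,
                        haplotype_index=hap,
                        chrom=chrom,
                        start=positions[run_start] - 1,
                        end=positions[i - 1],
                        ancestry=code_map[code],
                        certainty=1.0,
                    )
                )
                run_start = i
    return segments


def write_ancestry_segments(
    segments: Iterable[AncestrySegment], path: str | Path
) -> None:
    """Write segments in the segment_tsv dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("#individual\thaplotype\tchrom\tstart\tend\tancestry\tcertainty\n")
        for s in sorted(
            segments, key=lambda s: (s.individual_id, s.haplotype_index, s.chrom, s.start)
        ):
            fh.write(
                f"{s.individual_id}\t{s.haplotype_index}\t{s.chrom}\t"
                f"{s.start}\t{s.end}\t{s.ancestry}\t{s.certainty:g}\n"
            )


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------


def read_gene_annotations(
    path: str | Path, autosomal_only: bool = True
) -> list[GeneAnnotation]:
    """Read BED3+ gene annotations (column 4 = gene id).

    Returns genes sorted by (chrom, start).  Duplicate gene ids are rejected;
    sex-chromosome and mitochondrial genes are dropped when ``autosomal_only``.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: need >=4 BED columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "unknown"
            if autosomal_only and chrom in _NON_AUTOSOMAL:
                continue
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            try:
                genes.append(GeneAnnotation(name, chrom, start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------


def call_gene_ancestry_genotypes(
    segments: Sequence[AncestrySegment],
    genes: Sequence[GeneAnnotation],
    min_certainty: float = 0.99,
    population_id: str = "pop",
) -> AncestryGenotypeMatrix:
    """Assign a per-gene ancestry label to each haplotype of each individual.

    A haplotype receives a label at a gene iff the gene interval is fully
    contained in a single segment whose certainty is at least
    ``min_certainty``; otherwise that haplotype is unassigned at the gene.
    This containment rule is conservative: genes straddling an ancestry
    switch, or covered only by low-confidence calls, get no assignment.
    """
    if min_certainty < 0:
        raise ValueError(f"min_certainty must be >= 0, got {min_certainty}")
    individuals = sorted({s.individual_id for s in segments})
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    haps = np.full((len(genes), len(individuals), 2), MISSING, dtype=np.int8)

    # index segments per (individual, hap, chrom), sorted by start
    by_hap: dict[tuple[str, int, str], list[AncestrySegment]] = {}
    for s in segments:
        if s.certainty < min_certainty:
            continue
        by_hap.setdefault((s.individual_id, s.haplotype_index, s.chrom), []).append(s)
    starts: dict[tuple[str, int, str], list[int]] = {}
    for key, segs in by_hap.items():
        segs.sort(key=lambda s: s.start)
        starts[key] = [s.start for s in segs]

    for gi, gene in enumerate(genes):
        for ind in individuals:
            ni = ind_index[ind]
            for hap in (0, 1):
                key = (ind, hap, gene.chrom)
                segs = by_hap.get(key)
                if not segs:
                    continue
                # candidate: last segment starting at or before gene.start
                j = bisect_right(starts[key], gene.start) - 1
                if j >= 0 and segs[j].end >= gene.end:
                    haps[gi, ni, hap] = ANCESTRY_CODE[segs[j].ancestry]
    return AncestryGenotypeMatrix(population_id, [g.gene_id for g in genes],
                                  individuals, haps)


def apply_ancestry_genotype_threshold(
    matrix: AncestryGenotypeMatrix,
) -> tuple[AncestryGenotypeMatrix, float]:
    """Drop genes callable in too few individuals.

    Computes the mean and standard deviation (ddof=1) of the per-gene counts
    of individuals with a full ancestry pair, and retains genes strictly
    above ``mean - sd``.  With a degenerate spread (sd = 0, including the
    single-gene case) the rule becomes ``n_g >= mean`` so that uniform
    matrices are retained whole.
    """
    n_g = matrix.n_pairs.astype(float)
    if n_g.size == 0 or n_g.max() == 0:
        raise ValidationError("no callable genes: all genes lack full ancestry pairs")
    mean = float(n_g.mean())
    sd = float(n_g.std(ddof=1)) if n_g.size > 1 else 0.0
    threshold = mean - sd
    if sd > 0:
        keep = np.flatnonzero(n_g > threshold)
    else:
        keep = np.flatnonzero(n_g >= mean)
    logger.info(
        "%s: ancestry genotype threshold %.3f (mean %.3f, sd %.3f); "
        "%d/%d genes retained",
        matrix.population_id, threshold, mean, sd, keep.size, n_g.size,
    )
    return matrix.subset_genes(keep), threshold
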