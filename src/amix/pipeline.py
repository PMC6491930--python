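"""End-to-end AMI workflow: files in, result tables and a manifest out.

Stages: read local-ancestry segments per population -> call per-gene
ancestry genotypes -> apply the ancestry-genotype threshold -> filter and
LD-prune phenotype gene sets -> per-gene AMI tables -> Mantel-Haenszel
meta-analysis per gene set -> BH q-values over the whole run's family of
(phenotype x population) tests -> ancestry-driver (AH) profiles and
global-ancestry CVs -> optional permutation nulls -> cross-population AMI
variance.  Every stage count is recorded in a JSON manifest; a failure in
any stage aborts the run with a stage-named error and removes partial
outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ami_core import (
    ami_cross_population_variance,
    bh_qvalues,
    gene_ami,
    gene_count_tables,
    meta_ami,
)
from .ancestry_drivers import ancestry_cv, ancestry_homozygosity, \
    global_fractions_from_local
from .ancestry_io import (
    apply_ancestry_genotype_threshold,
    call_gene_ancestry_genotypes,
    read_ancestry_segments,
    read_gene_annotations,
)
from .gene_sets import filter_gene_sets, ld_prune_gene_sets, read_gene_sets, \
    read_ld_table
from .permutation_nulls import PermutationConfig, empirical_p, \
    random_geneset_null, random_mating_permutation

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(slots=True)
class RunConfig:
    """Configuration of one analysis run (loadable from YAML)."""

    populations: dict[str, Path]  # population id -> segment TSV
    genes_bed: Path
    gene_sets_gmt: Path
    ld_table: Path | None = None
    min_certainty: float = 0.99
    r2_max: float = 0.1
    min_set_size: int = 2
    n_virtual_diploids: int = 10_000
    n_gene_set_perms: int = 1_000
    run_random_mating_null: bool = True
    run_geneset_null: bool = True
    output_dir: Path = Path("results")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _p(x: str) -> Path:
            p = Path(x)
            return p if p.is_absolute() else base / p

        return cls(
            populations={k: _p(v) for k, v in raw["populations"].items()},
            genes_bed=_p(raw["genes_bed"]),
            gene_sets_gmt=_p(raw["gene_sets_gmt"]),
            ld_table=_p(raw["ld_table"]) if raw.get("ld_table") else None,
            min_certainty=float(raw.get("min_certainty", 0.99)),
            r2_max=float(raw.get("r2_max", 0.1)),
            min_set_size=int(raw.get("min_set_size", 2)),
            n_virtual_diploids=int(raw.get("n_virtual_diploids", 10_000)),
            n_gene_set_perms=int(raw.get("n_gene_set_perms", 1_000)),
            run_random_mating_null=bool(raw.get("run_random_mating_null", True)),
            run_geneset_null=bool(raw.get("run_geneset_null", True)),
            output_dir=_p(str(raw.get("output_dir", "results"))),
            seed=int(raw.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        missing = [
            str(p)
            for p in [self.genes_bed, self.gene_sets_gmt, self.ld_table,
                      *self.populations.values()]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("missing input path(s): " + ", ".join(missing))


def run_ami(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary.

    Writes per_gene_ami.tsv, per_phenotype.tsv, drivers.tsv,
    ancestry_cv.tsv, global_fractions.tsv, cross_population_variance.tsv
    (>= 2 populations), optional null-distribution TSVs, and manifest.json
    under ``config.output_dir``.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    try:
        return _run(config, outdir, _write, written)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(f"run_ami failed: {exc}") from exc


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}': {exc}") from exc
        return wrapped
    return deco


def _run(config: RunConfig, outdir: Path, _write, written: list[Path]) -> dict:
    manifest: dict = {
        "amix_version": __version__,
        "seed": config.seed,
        "min_certainty": config.min_certainty,
        "r2_max": config.r2_max,
        "min_set_size": config.min_set_size,
        "populations": {},
    }

    genes = _stage("read_gene_annotations")(read_gene_annotations)(config.genes_bed)
    sets_raw = _stage("read_gene_sets")(read_gene_sets)(config.gene_sets_gmt)
    ld = (
        _stage("read_ld_table")(read_ld_table)(config.ld_table)
        if config.ld_table
        else {}
    )
    manifest["n_genes_annotated"] = len(genes)
    manifest["n_gene_sets_input"] = len(sets_raw)

    per_gene_rows: list[dict] = []
    pheno_rows: list[dict] = []
    driver_rows: list[dict] = []
    cv_rows: list[dict] = []
    frac_rows: list[pd.DataFrame] = []
    null_mating_rows: list[pd.DataFrame] = []
    geneset_nulls: dict[tuple[str, str], np.ndarray] = {}  # (pop, pheno) -> draws

    for pop_i, (pop, seg_path) in enumerate(sorted(config.populations.items())):
        pm: dict = {}
        segments = _stage(f"read_segments[{pop}]")(read_ancestry_segments)(seg_path)
        pm["n_segments"] = len(segments)
        matrix = _stage(f"call_genotypes[{pop}]")(call_gene_ancestry_genotypes)(
            segments, genes, config.min_certainty, population_id=pop
        )
        pm["n_individuals"] = len(matrix.individuals)
        matrix, threshold = _stage(f"threshold[{pop}]")(
            apply_ancestry_genotype_threshold
        )(matrix)
        pm["ancestry_genotype_threshold"] = threshold
        pm["n_genes_callable"] = len(matrix.genes)

        sets = _stage(f"filter_sets[{pop}]")(filter_gene_sets)(
            sets_raw, matrix.genes, config.min_set_size
        )
        pm["n_sets_after_filter"] = len(sets)
        if ld:
            sets = _stage(f"ld_prune[{pop}]")(ld_prune_gene_sets)(
                sets, ld, config.r2_max, config.min_set_size
            )
        pm["n_sets_after_prune"] = len(sets)

        tables = _stage(f"gene_tables[{pop}]")(gene_count_tables)(matrix)
        pm["n_genes_informative"] = len(tables)
        for t in tables.values():
            ami = gene_ami(t)
            per_gene_rows.append({
                "population": pop, "gene_id": t.gene_id,
                "obs_hom": t.obs_hom, "obs_het": t.obs_het,
                "exp_hom": t.exp_hom, "exp_het": t.exp_het,
                "n_pairs": t.n_pairs, "ami": ami.value,
                "corrected": ami.corrected,
            })

        perm_cfg = PermutationConfig(
            n_virtual_diploids=config.n_virtual_diploids,
            n_gene_set_perms=config.n_gene_set_perms,
            # distinct deterministic substream per population
            seed=(config.seed * 1_000_003 + pop_i) % 2**31,
        )
        null_by_size: dict[int, np.ndarray] = {}
        for s in sets:
            gene_tables_s = [tables[g] for g in s.gene_ids if g in tables]
            if not gene_tables_s:
                logger.info("%s/%s: no informative genes; skipped", pop, s.phenotype_id)
                continue
            res = _stage(f"meta_ami[{pop}]")(meta_ami)(
                gene_tables_s, s.phenotype_id, pop
            )
            row = {
                "population": pop, "phenotype": s.phenotype_id,
                "category": s.category, "k_genes": res.k_genes,
                "pooled_log_or": res.pooled_log_or, "se": res.se,
                "ci95_low": res.ci95[0], "ci95_high": res.ci95[1],
                "p_value": res.p_value,
            }
            if config.run_geneset_null:
                k = res.k_genes
                if k not in null_by_size:
                    null_by_size[k] = _stage(f"geneset_null[{pop}]")(
                        random_geneset_null
                    )(list(tables.values()), k, perm_cfg)
                geneset_nulls[(pop, s.phenotype_id)] = null_by_size[k]
                row["perm_p"] = empirical_p(res.pooled_log_or, null_by_size[k])
            pheno_rows.append(row)

            ah = _stage(f"drivers[{pop}]")(ancestry_homozygosity)(s, matrix, pop)
            for anc in ah.ah:
                driver_rows.append({
                    "population": pop, "phenotype": s.phenotype_id,
                    "ancestry": anc, "ah": ah.ah[anc],
                    "ah_absolute": ah.ah_absolute[anc],
                    "ah_per_gene": ah.ah_per_gene[anc],
                    "n_genes": ah.n_genes[anc],
                })

        fractions = _stage(f"global_fractions[{pop}]")(
            global_fractions_from_local
        )(matrix=matrix)
        frac_rows.append(fractions.assign(population=pop,
                                          individual=fractions.index))
        cv = _stage(f"ancestry_cv[{pop}]")(ancestry_cv)(fractions, pop)
        for anc in cv.cv:
            cv_rows.append({
                "population": pop, "ancestry": anc, "mean": cv.mean[anc],
                "sd": cv.sd[anc], "cv": cv.cv[anc],
                "raw_variance": cv.raw_variance[anc],
            })

        if config.run_random_mating_null:
            null = _stage(f"random_mating_null[{pop}]")(
                random_mating_permutation
            )(matrix, perm_cfg)
            null_mating_rows.append(null.per_gene.assign(population=pop))
            pm["random_mating_null_mean"] = null.mean
            pm["random_mating_null_sd"] = null.sd

        manifest["populations"][pop] = pm

    if not pheno_rows:
        raise StageError("stage 'meta_ami': no phenotype survived filtering "
                         "in any population")

    pheno = pd.DataFrame(pheno_rows)
    pheno["q_value"] = bh_qvalues(pheno["p_value"].to_numpy())
    _write(pd.DataFrame(per_gene_rows), "per_gene_ami.tsv")
    _write(pheno, "per_phenotype.tsv")
    _write(pd.DataFrame(driver_rows), "drivers.tsv")
    _write(pd.DataFrame(cv_rows), "ancestry_cv.tsv")
    _write(pd.concat(frac_rows, ignore_index=True), "global_fractions.tsv")
    if null_mating_rows:
        _write(pd.concat(null_mating_rows, ignore_index=True),
               "random_mating_null.tsv")

    if len(config.populations) >= 2:
        wide = pheno.pivot(index="phenotype", columns="population",
                           values="pooled_log_or")
        wide = wide.dropna(axis=0)
        if len(wide) >= 2:
            null_vars = None
            if config.run_geneset_null:
                pops = list(wide.columns)
                null_vars = {}
                for pheno_id in wide.index:
                    draws = [geneset_nulls.get((p, pheno_id)) for p in pops]
                    if all(d is not None for d in draws):
                        null_vars[pheno_id] = np.stack(draws).var(axis=0, ddof=1)
            records = _stage("cross_population_variance")(
                ami_cross_population_variance
            )(wide, null_vars)
            _write(
                pd.DataFrame([{
                    "phenotype": r.phenotype_id,
                    "raw_variance": r.raw_variance,
                    "normalized_variance": r.normalized_variance,
                    "p_value": r.p_value, "q_value": r.q_value,
                } for r in records]),
                "cross_population_variance.tsv",
            )

    manifest["n_phenotype_tests"] = len(pheno)
    manifest["n_significant_q05"] = int((pheno["q_value"] < 0.05).sum())
    manifest["outputs"] = [p.name for p in written]
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(manifest_path)
    return manifest
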