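"""Permutation controls for the AMI.

Two nulls calibrate the statistic:

* **Random-mating permutation** — per gene, the observed haplotype ancestry
  labels are pooled and re-paired uniformly at random (with replacement)
  into a large cohort of virtual diploids.  Recomputing the AMI on these
  virtual genotypes yields the per-gene AMI distribution expected under
  random mating, which is narrow and centered at zero.

* **Random gene-set permutation** — genome-wide ancestry-based assortment
  shifts *every* gene's AMI, so a trait-specific signal must exceed the
  genome-wide background.  Drawing many random gene sets of the same size
  as a trait set and pooling each with the Mantel-Haenszel estimator gives
  the background null for that set size; an add-one two-sided empirical
  p-value locates the observed pooled AMI in it.

One seed drives both procedures through independent substreams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ami_core import (
    GeneCountTable,
    gene_ami,
    hw_expected_counts,
    locus_ancestry_fractions,
    meta_ami,
)
from .ancestry_io import AncestryGenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class PermutationConfig:
    n_virtual_diploids: int = 10_000
    n_gene_set_perms: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_virtual_diploids < 1 or self.n_gene_set_perms < 1:
            raise ValueError("permutation counts must be >= 1")

    def substreams(self) -> tuple[np.random.Generator, np.random.Generator]:
        """Independent generators for the two procedures."""
        ss = np.random.SeedSequence(self.seed)
        mating, genesets = ss.spawn(2)
        return np.random.default_rng(mating), np.random.default_rng(genesets)


@dataclass(slots=True)
class RandomMatingNull:
    """Per-gene AMI under random re-pairing of haplotypes."""

    per_gene: pd.DataFrame  # columns: gene_id, null_ami, corrected
    mean: float
    sd: float


def random_mating_permutation(
    matrix: AncestryGenotypeMatrix,
    cfg: PermutationConfig,
) -> RandomMatingNull:
    """Expected per-gene AMI under random mating.

    For each gene, the 2*n_pairs haplotype labels of fully-assigned
    individuals are pooled and paired uniformly at random with replacement
    into ``cfg.n_virtual_diploids`` virtual individuals; the AMI of the
    virtual cohort is computed against HW expectations from the same pooled
    fractions.  Genes fixed for one ancestry (AMI undefined) or with fewer
    than two assigned haplotypes are excluded.
    """
    rng, _ = cfg.substreams()
    m = cfg.n_virtual_diploids
    rows = []
    for gi, gid in enumerate(matrix.genes):
        row = matrix.haps[gi]
        full = (row >= 0).all(axis=1)
        pool = row[full].ravel()
        if pool.size < 2:
            logger.debug("%s: <2 assigned haplotypes; excluded from null", gid)
            continue
        frac = locus_ancestry_fractions(matrix, gi)
        exp_hom, exp_het = hw_expected_counts(frac, m)
        if exp_hom <= 0 or exp_het <= 0:
            logger.debug("%s: fixed locus; AMI undefined under null", gid)
            continue
        virt = rng.choice(pool, size=(m, 2), replace=True)
        obs_hom = int((virt[:, 0] == virt[:, 1]).sum())
        table = GeneCountTable(gid, obs_hom, m - obs_hom, exp_hom, exp_het)
        ami = gene_ami(table)
        rows.append((gid, ami.value, ami.corrected))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "null_ami", "corrected"])
    if per_gene.empty:
        raise ValueError("no gene admits a random-mating null")
    return RandomMatingNull(
        per_gene=per_gene,
        mean=float(per_gene["null_ami"].mean()),
        sd=float(per_gene["null_ami"].std(ddof=1)) if len(per_gene) > 1 else 0.0,
    )


def random_geneset_null(
    tables: Sequence[GeneCountTable],
    set_size: int,
    cfg: PermutationConfig,
) -> np.ndarray:
    """Null distribution of pooled log odds ratios from random gene sets.

    Draws ``cfg.n_gene_set_perms`` gene subsets of ``set_size`` without
    replacement (within each draw) from the genome-wide pool of informative
    genes and pools each with the Mantel-Haenszel estimator.
    """
    if set_size > len(tables):
        raise ValueError(
            f"set_size {set_size} exceeds pool of {len(tables)} genes"
        )
    _, rng = cfg.substreams()
    tables = list(tables)
    null = np.empty(cfg.n_gene_set_perms)
    for i in range(cfg.n_gene_set_perms):
        idx = rng.choice(len(tables), size=set_size, replace=False)
        null[i] = meta_ami([tables[j] for j in idx]).pooled_log_or
    return null


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Two-sided add-one empirical p-value: extremeness in absolute value.

    The add-one convention keeps p in (0, 1]; an observation beyond every
    null draw scores 1 / (n + 1), never zero.
    """
    null = np.asarray(null, dtype=float)
    n = null.size
    return float((1 + (np.abs(null) >= abs(observed)).sum()) / (n + 1))
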