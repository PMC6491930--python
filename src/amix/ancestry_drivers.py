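"""Ancestry-specific drivers of assortative mating.

A positive pooled AMI says *that* a gene set shows excess ancestry
homozygosity; the AH statistic says *which* ancestry drives it.  For a
phenotype gene set and one ancestry, AH sums the relative excess of
observed over HW-expected homozygotes of that ancestry across the set's
genes:

    AH_anc = sum_g (obs_g_anc - exp_g_anc) / exp_g_anc

where obs_g_anc counts individuals homozygous for anc at gene g and
exp_g_anc = (fraction of anc at g)^2 * n_pairs_g.  Each per-gene term is
at least -1, so AH is bounded below by minus the number of genes; AH = 0
when observation matches expectation everywhere.

The module also summarizes inter-individual global-ancestry variation with
the coefficient of variation (CV), since assortment on an ancestry inflates
the spread of that ancestry's fractions across individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ami_core import locus_ancestry_fractions
from .ancestry_io import ANCESTRIES, AncestryGenotypeMatrix, AncestrySegment
from .gene_sets import GeneSet

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class AHProfile:
    """Per-ancestry relative homozygosity excess for one gene set."""

    phenotype_id: str
    population_id: str
    ah: dict[str, float]  # sum over genes of (obs - exp) / exp
    ah_absolute: dict[str, float]  # companion: sum of obs - exp (count scale)
    ah_per_gene: dict[str, float]  # mean per contributing gene
    n_genes: dict[str, int]  # genes contributing per ancestry


@dataclass(slots=True)
class AncestryVarianceSummary:
    """Spread of per-individual global ancestry fractions in one population."""

    population_id: str
    mean: dict[str, float]
    sd: dict[str, float]
    cv: dict[str, float]  # NaN where the mean fraction is 0
    raw_variance: dict[str, float]


def ancestry_homozygosity(
    gene_set: GeneSet,
    matrix: AncestryGenotypeMatrix,
    population_id: str | None = None,
) -> AHProfile:
    """AH decomposition of a gene set's homozygosity excess by ancestry.

    Genes where an ancestry has zero expected homozygotes (fraction 0 at
    that locus) are skipped for that ancestry and logged.
    """
    if not gene_set.gene_ids:
        raise ValueError("empty gene set")
    ah = {a: 0.0 for a in ANCESTRIES}
    ah_abs = {a: 0.0 for a in ANCESTRIES}
    n_genes = {a: 0 for a in ANCESTRIES}
    for gid in gene_set.gene_ids:
        gi = matrix.gene_index(gid)
        row = matrix.haps[gi]
        full = (row >= 0).all(axis=1)
        n_pairs = int(full.sum())
        if n_pairs == 0:
            logger.info("%s: no full pairs at %s; skipped", gene_set.phenotype_id, gid)
            continue
        frac = locus_ancestry_fractions(matrix, gi)
        hom_codes = row[full][row[full, 0] == row[full, 1], 0]
        obs_by_anc = np.bincount(hom_codes, minlength=3)
        for k, anc in enumerate(ANCESTRIES):
            exp = frac[k] ** 2 * n_pairs
            if exp == 0:
                logger.debug("%s at %s: fraction 0, term skipped", anc, gid)
                continue
            ah[anc] += (obs_by_anc[k] - exp) / exp
            ah_abs[anc] += obs_by_anc[k] - exp
            n_genes[anc] += 1
    per_gene = {
        a: (ah[a] / n_genes[a]) if n_genes[a] else float("nan") for a in ANCESTRIES
    }
    return AHProfile(
        phenotype_id=gene_set.phenotype_id,
        population_id=population_id or matrix.population_id,
        ah=ah,
        ah_absolute=ah_abs,
        ah_per_gene=per_gene,
        n_genes=n_genes,
    )


def global_fractions_from_local(
    matrix: AncestryGenotypeMatrix | None = None,
    segments: list[AncestrySegment] | None = None,
) -> pd.DataFrame:
    """Per-individual global ancestry fractions from local assignments.

    Matrix mode: fraction of assigned gene-haplotypes per ancestry
    (single assignments count too).  Segment mode: fraction of assigned bp.
    Rows are individuals, columns AFR/EUR/NAT; fractions sum to 1 over the
    assigned material.  Individuals with nothing assigned are excluded.
    """
    if (matrix is None) == (segments is None):
        raise ValueError("supply exactly one of matrix or segments")
    rows: dict[str, np.ndarray] = {}
    if matrix is not None:
        for ni, ind in enumerate(matrix.individuals):
            labels = matrix.haps[:, ni, :].ravel()
            labels = labels[labels >= 0]
            if labels.size == 0:
                logger.info("%s: no assigned haplotypes; excluded", ind)
                continue
            rows[ind] = np.bincount(labels, minlength=3) / labels.size
    else:
        bp: dict[str, np.ndarray] = {}
        for s in segments:
            arr = bp.setdefault(s.individual_id, np.zeros(3))
            arr[ANCESTRIES.index(s.ancestry)] += s.end - s.start
        for ind, arr in bp.items():
            total = arr.sum()
            if total == 0:
                logger.info("%s: no assigned bp; excluded", ind)
                continue
            rows[ind] = arr / total
    if not rows:
        raise ValueError("no individual has any ancestry assignment")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(ANCESTRIES))


def ancestry_cv(
    fractions: pd.DataFrame, population_id: str = "pop"
) -> AncestryVarianceSummary:
    """Coefficient of variation (sd/mean, ddof=1) of global ancestry fractions.

    CV is scale-free, so ancestries present at very different mean levels
    can be compared; it is undefined (NaN, flagged in the log) for an
    ancestry entirely absent from the population.
    """
    if len(fractions) < 2:
        raise ValueError("need >= 2 individuals for a coefficient of variation")
    mean = fractions.mean()
    sd = fractions.std(ddof=1)
    cv = {}
    for anc in ANCESTRIES:
        if mean[anc] == 0:
            logger.info("%s: ancestry %s absent; CV undefined", population_id, anc)
            cv[anc] = float("nan")
        else:
            cv[anc] = float(sd[anc] / mean[anc])
    return AncestryVarianceSummary(
        population_id=population_id,
        mean={a: float(mean[a]) for a in ANCESTRIES},
        sd={a: float(sd[a]) for a in ANCESTRIES},
        cv=cv,
        raw_variance={a: float(sd[a] ** 2) for a in ANCESTRIES},
    )
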