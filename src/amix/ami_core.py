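"""The Assortative Mating Index (AMI) and its gene-set meta-analysis.

Assortative mating on local ancestry leaves an excess of *ancestry
homozygosity*: individuals carrying the same continental ancestry on both
copies of a gene more often than random mating predicts.  The AMI measures
this per gene as a log odds ratio contrasting observed homozygote and
heterozygote counts with their expectations under a triallelic
Hardy-Weinberg (HW) model, in which the three locus-specific ancestry
fractions (a, e, n) play the role of allele frequencies:

    exp(hom) = (a^2 + e^2 + n^2) * n_pairs
    exp(het) = (2ae + 2an + 2en) * n_pairs
    AMI      = ln[ (obs_hom / exp_hom) / (obs_het / exp_het) ]

Positive AMI indicates assortative, negative disassortative mating.

For a polygenic phenotype the per-gene 2x2 tables (rows observed/expected,
columns hom/het) are pooled with the Mantel-Haenszel fixed-effects estimator;
the standard error of the pooled log odds ratio uses the
Robins-Breslow-Greenland variance and yields a normal-theory p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ancestry_io import ANCESTRIES, AncestryGenotypeMatrix

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class LocusAncestryFractions(NamedTuple):
    """Locus-specific ancestry fractions; the triallelic HW 'allele' freqs."""

    a: float  # African
    e: float  # European
    n: float  # Native American

    def validate(self) -> "LocusAncestryFractions":
        if min(self) < -1e-9 or abs(sum(self) - 1.0) > 1e-9:
            raise ValueError(f"invalid ancestry fractions {self}")
        return self

    @property
    def hom_freq(self) -> float:
        return self.a**2 + self.e**2 + self.n**2


@dataclass(frozen=True, slots=True)
class GeneCountTable:
    """Observed and HW-expected hom/het counts for one gene: the AMI 2x2."""

    gene_id: str
    obs_hom: int
    obs_het: int
    exp_hom: float
    exp_het: float

    @property
    def n_pairs(self) -> int:
        return self.obs_hom + self.obs_het

    def __post_init__(self) -> None:
        if min(self.obs_hom, self.obs_het) < 0 or min(self.exp_hom, self.exp_het) < 0:
            raise ValueError(f"negative cell in table for {self.gene_id}")
        if abs(self.exp_hom + self.exp_het - self.n_pairs) > 1e-6:
            raise ValueError(
                f"{self.gene_id}: expected counts sum {self.exp_hom + self.exp_het} "
                f"!= n_pairs {self.n_pairs}"
            )


@dataclass(slots=True)
class PhenotypeAMIResult:
    """Pooled AMI for one gene set in one population."""

    phenotype_id: str
    population_id: str
    pooled_log_or: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    q_value: float  # NaN until BH over the run's full family
    k_genes: int


class GeneAMI(NamedTuple):
    value: float
    corrected: bool  # Haldane-Anscombe +0.5 applied to a zero observed cell


# ---------------------------------------------------------------------------
# per-gene quantities
# ---------------------------------------------------------------------------


def locus_ancestry_fractions(
    matrix: AncestryGenotypeMatrix, gene_index: int
) -> LocusAncestryFractions:
    """Ancestry fractions at one gene, over fully-assigned individuals only.

    Counting only the 2 * n_pairs haplotypes of individuals with a full
    ancestry pair keeps the observed and expected counts referring to the
    same cohort.
    """
    row = matrix.haps[gene_index]
    full = (row >= 0).all(axis=1)
    labels = row[full].ravel()
    if labels.size == 0:
        raise ValueError(f"no ancestry pairs at locus {matrix.genes[gene_index]}")
    counts = np.bincount(labels, minlength=3)
    frac = counts / labels.size
    return LocusAncestryFractions(*frac.tolist())


def hw_expected_counts(
    f: LocusAncestryFractions, n_pairs: int
) -> tuple[float, float]:
    """Expected (hom, het) counts for n_pairs diploids under triallelic HW."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    f.validate()
    hom = f.hom_freq * n_pairs
    return hom, n_pairs - hom


def observed_counts(
    matrix: AncestryGenotypeMatrix, gene_index: int
) -> tuple[int, int, int]:
    """(obs_hom, obs_het, n_pairs) at one gene; singles and missing excluded."""
    row = matrix.haps[gene_index]
    full = (row >= 0).all(axis=1)
    hom = int((row[full, 0] == row[full, 1]).sum())
    n = int(full.sum())
    return hom, n - hom, n


def gene_count_tables(
    matrix: AncestryGenotypeMatrix,
) -> dict[str, GeneCountTable]:
    """Build the AMI 2x2 for every informative gene.

    Genes with no full pairs, or fixed for one ancestry (expected
    heterozygosity zero, so the odds ratio is undefined), are skipped with a
    log message.
    """
    tables: dict[str, GeneCountTable] = {}
    for gi, gid in enumerate(matrix.genes):
        obs_hom, obs_het, n = observed_counts(matrix, gi)
        if n == 0:
            logger.debug("%s: no full ancestry pairs; skipped", gid)
            continue
        f = locus_ancestry_fractions(matrix, gi)
        exp_hom, exp_het = hw_expected_counts(f, n)
        if exp_hom <= 0 or exp_het <= 0:
            logger.debug("%s: locus fixed for one ancestry; AMI undefined", gid)
            continue
        tables[gid] = GeneCountTable(gid, obs_hom, obs_het, exp_hom, exp_het)
    return tables


def gene_ami(t: GeneCountTable) -> GeneAMI:
    """Per-gene AMI log odds ratio.

    A zero observed cell makes the log undefined; the standard
    Haldane-Anscombe continuity correction (+0.5 to all four cells) is then
    applied and the value flagged as corrected.
    """
    if t.exp_hom <= 0 or t.exp_het <= 0:
        raise ValueError(f"{t.gene_id}: AMI undefined at a fixed locus")
    a, b, c, d = t.obs_hom, t.obs_het, t.exp_hom, t.exp_het
    corrected = a == 0 or b == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return GeneAMI(math.log((a / c) / (b / d)), corrected)


# ---------------------------------------------------------------------------
# Mantel-Haenszel meta-analysis
# ---------------------------------------------------------------------------


def meta_ami(
    tables: Sequence[GeneCountTable],
    phenotype_id: str = "",
    population_id: str = "",
) -> PhenotypeAMIResult:
    """Pool per-gene AMI 2x2 tables into one fixed-effects log odds ratio.

    Each gene is a stratum with rows {observed, expected} and columns
    {hom, het}.  The pooled odds ratio is the Mantel-Haenszel estimator

        OR_MH = sum_g(a_g d_g / N_g) / sum_g(b_g c_g / N_g)

    with a=obs_hom, b=obs_het, c=exp_hom, d=exp_het and N the table total.
    The expected cells are real-valued (HW frequencies times counts, not
    rounded) and enter the formulas as-is.  The SE of ln(OR_MH) is the
    Robins-Breslow-Greenland variance estimate; p is two-sided normal.

    If every stratum has a zero observed cell on the same side the pooled
    numerator or denominator vanishes; the continuity-corrected tables
    (+0.5 everywhere) are then pooled instead.
    """
    if not tables:
        raise ValueError("empty phenotype after filtering")
    cells = np.array(
        [[t.obs_hom, t.obs_het, t.exp_hom, t.exp_het] for t in tables], dtype=float
    )
    log_or, se = _mh_log_or_se(cells)
    if not math.isfinite(log_or):
        cells = cells + 0.5
        log_or, se = _mh_log_or_se(cells)
        logger.info(
            "%s/%s: zero pooled cell; continuity correction applied in pooling",
            population_id, phenotype_id,
        )
    z = log_or / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return PhenotypeAMIResult(
        phenotype_id=phenotype_id,
        population_id=population_id,
        pooled_log_or=log_or,
        se=se,
        ci95=(log_or - Z_95 * se, log_or + Z_95 * se),
        p_value=float(min(p, 1.0)),
        q_value=float("nan"),
        k_genes=len(tables),
    )


def _mh_log_or_se(cells: np.ndarray) -> tuple[float, float]:
    """Mantel-Haenszel pooled log OR and RBG standard error.

    ``cells`` is (k, 4): columns a, b, c, d per stratum.
    """
    a, b, c, d = cells.T
    n_tot = cells.sum(axis=1)
    r = a * d / n_tot
    s = b * c / n_tot
    r_sum, s_sum = r.sum(), s.sum()
    if r_sum <= 0 or s_sum <= 0:
        return float("inf") if s_sum <= 0 else float("-inf"), float("nan")
    log_or = math.log(r_sum / s_sum)
    p = (a + d) / n_tot
    q = (b + c) / n_tot
    var = (
        (p * r).sum() / (2 * r_sum**2)
        + ((p * s + q * r).sum()) / (2 * r_sum * s_sum)
        + (q * s).sum() / (2 * s_sum**2)
    )
    return log_or, math.sqrt(var)


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one declared test family.

    The family is all (phenotype x population) tests of a run; callers
    collect every p-value first and correct once.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_ami_distributions(
    observed: Sequence[float],
    expected: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test of mean observed vs expected AMI (Welch by default)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size < 2 or exp.size < 2:
        raise ValueError("need >= 2 values per sample")
    if obs.std() == 0 and exp.std() == 0:
        return (0.0, 1.0) if obs.mean() == exp.mean() else (math.inf, 0.0)
    t, p = stats.ttest_ind(obs, exp, equal_var=equal_var)
    return float(t), float(p)


@dataclass(slots=True)
class AMIVarianceRecord:
    """Cross-population spread of one phenotype's pooled AMI."""

    phenotype_id: str
    raw_variance: float
    normalized_variance: float
    p_value: float = float("nan")
    q_value: float = float("nan")


def ami_cross_population_variance(
    ami: pd.DataFrame,
    null_variances: Mapping[str, np.ndarray] | None = None,
) -> list[AMIVarianceRecord]:
    """Variance of pooled AMI across populations, per phenotype.

    ``ami`` is phenotype x population (pooled log odds ratios).  Phenotypes
    with any missing population value are excluded.  Raw variances (ddof=1)
    are normalized by the mean raw variance over all retained phenotypes,
    so the average phenotype scores 1.  When per-phenotype null variance
    draws are supplied (from random same-size gene sets), a two-sided
    add-one empirical p-value locates each observed variance in its null.
    """
    if ami.shape[1] < 2:
        raise ValueError("need >= 2 populations for cross-population variance")
    complete = ami.dropna(axis=0)
    dropped = set(ami.index) - set(complete.index)
    if dropped:
        logger.info("excluded phenotypes with missing AMI: %s", sorted(dropped))
    if complete.empty:
        raise ValueError("no phenotype has AMI in every population")
    raw = complete.var(axis=1, ddof=1)
    mean_raw = raw.mean()
    norm = raw / mean_raw if mean_raw > 0 else raw * 0.0 + 1.0
    records = []
    for pheno in complete.index:
        rec = AMIVarianceRecord(pheno, float(raw[pheno]), float(norm[pheno]))
        if null_variances is not None and pheno in null_variances:
            null = np.asarray(null_variances[pheno], dtype=float)
            n = null.size
            p_hi = (1 + (null >= rec.raw_variance).sum()) / (n + 1)
            p_lo = (1 + (null <= rec.raw_variance).sum()) / (n + 1)
            rec.p_value = min(1.0, 2.0 * min(p_hi, p_lo))
        records.append(rec)
    ps = [r.p_value for r in records]
    if null_variances is not None and all(math.isfinite(p) for p in ps):
        qs = bh_qvalues(ps)
        for r, q in zip(records, qs):
            r.q_value = float(q)
    return records
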