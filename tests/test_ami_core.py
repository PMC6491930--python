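import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amix.ami_core import (
    GeneCountTable,
    LocusAncestryFractions,
    _mh_log_or_se,
    ami_cross_population_variance,
    bh_qvalues,
    compare_ami_distributions,
    gene_ami,
    gene_count_tables,
    hw_expected_counts,
    locus_ancestry_fractions,
    meta_ami,
    observed_counts,
)
from conftest import make_matrix


def mh_oracle(cells):
    """Independent exact Mantel-Haenszel pooled OR via rational arithmetic."""
    num = Fraction(0)
    den = Fraction(0)
    for a, b, c, d in cells:
        n = Fraction(a + b + c + d)
        num += Fraction(a) * Fraction(d) / n
        den += Fraction(b) * Fraction(c) / n
    return num / den


class TestFractions:
    def test_fixed_locus(self):
        m = make_matrix([[("AFR", "AFR")] * 4])
        assert locus_ancestry_fractions(m, 0) == (1.0, 0.0, 0.0)

    def test_symmetric_het(self):
        m = make_matrix([[("AFR", "EUR"), ("AFR", "EUR")]])
        assert locus_ancestry_fractions(m, 0) == (0.5, 0.5, 0.0)

    def test_hand_count_of_eight_haplotypes(self):
        m = make_matrix(
            [[("AFR", "AFR"), ("AFR", "EUR"), ("EUR", "NAT"), ("NAT", "NAT")]]
        )
        assert locus_ancestry_fractions(m, 0) == (3 / 8, 2 / 8, 3 / 8)

    def test_singles_excluded_from_fractions(self):
        m = make_matrix([[("AFR", "AFR"), ("EUR",), ()]])
        assert locus_ancestry_fractions(m, 0) == (1.0, 0.0, 0.0)

    def test_empty_locus_is_error(self):
        m = make_matrix([[(), ("EUR",)]])
        with pytest.raises(ValueError, match="no ancestry pairs"):
            locus_ancestry_fractions(m, 0)


class TestHWExpectation:
    @pytest.mark.parametrize(
        "f, n, hom, het",
        [
            ((1, 0, 0), 50, 50, 0),
            ((1 / 3, 1 / 3, 1 / 3), 90, 30, 60),
            ((0.5, 0.3, 0.2), 100, 38, 62),
        ],
    )
    def test_known_values(self, f, n, hom, het):
        eh, et = hw_expected_counts(LocusAncestryFractions(*f), n)
        assert eh == pytest.approx(hom, abs=1e-9)
        assert et == pytest.approx(het, abs=1e-9)

    def test_grid_matches_ordered_pair_enumeration(self):
        """exp_hom from a^2+e^2+n^2 equals summing the 9 ordered ancestry
        pairs restricted to identical labels, on the full 0.1-grid simplex."""
        for ia in range(11):
            for ie in range(11 - ia):
                a, e = ia / 10, ie / 10
                n = 1 - a - e
                f = LocusAncestryFractions(a, e, n)
                freqs = [a, e, n]
                hom_enum = sum(
                    freqs[x] * freqs[y]
                    for x, y in itertools.product(range(3), repeat=2)
                    if x == y
                )
                eh, et = hw_expected_counts(f, 1000)
                assert eh == pytest.approx(hom_enum * 1000, abs=1e-9)
                assert eh + et == pytest.approx(1000, abs=1e-9)


class TestObservedCounts:
    def test_all_hom(self):
        m = make_matrix([[("AFR", "AFR"), ("EUR", "EUR")]])
        assert observed_counts(m, 0) == (2, 0, 2)

    def test_all_het(self):
        m = make_matrix([[("AFR", "EUR")] * 5])
        assert observed_counts(m, 0) == (0, 5, 5)

    def test_mixed_matches_enumeration(self):
        cells = [
            ("AFR", "AFR"), ("AFR", "EUR"), ("EUR", "EUR"), ("NAT", "NAT"),
            ("EUR", "NAT"), ("AFR", "NAT"), ("AFR", "AFR"), ("EUR",), (),
            ("NAT", "EUR"),
        ]
        m = make_matrix([cells])
        hom = sum(1 for c in cells if len(c) == 2 and c[0] == c[1])
        het = sum(1 for c in cells if len(c) == 2 and c[0] != c[1])
        assert observed_counts(m, 0) == (hom, het, hom + het)


class TestGeneAMI:
    def test_identity_when_obs_equals_exp(self):
        t = GeneCountTable("g", 38, 62, 38.0, 62.0)
        assert gene_ami(t) == (0.0, False)

    def test_hand_value(self):
        t = GeneCountTable("g", 60, 40, 50.0, 50.0)
        assert gene_ami(t).value == pytest.approx(math.log(1.5), abs=1e-12)

    def test_antisymmetry_under_hom_het_exchange(self):
        t1 = GeneCountTable("g", 60, 40, 50.0, 50.0)
        t2 = GeneCountTable("g", 40, 60, 50.0, 50.0)
        assert gene_ami(t1).value == pytest.approx(-gene_ami(t2).value, abs=1e-12)

    def test_zero_cell_flagged_corrected(self):
        t = GeneCountTable("g", 0, 10, 4.0, 6.0)
        value, corrected = gene_ami(t)
        assert corrected and math.isfinite(value)

    def test_fixed_locus_rejected(self):
        with pytest.raises(ValueError, match="fixed locus"):
            gene_ami(GeneCountTable("g", 10, 0, 10.0, 0.0))

    def test_fixed_locus_skipped_by_table_builder(self):
        m = make_matrix([[("AFR", "AFR")] * 3, [("AFR", "EUR")] * 3])
        tables = gene_count_tables(m)
        assert list(tables) == ["G2"]


class TestMetaAMI:
    def test_single_stratum_equals_gene_ami(self):
        t = GeneCountTable("g", 60, 40, 50.0, 50.0)
        res = meta_ami([t])
        assert res.pooled_log_or == pytest.approx(gene_ami(t).value, abs=1e-12)
        assert res.ci95[0] <= res.pooled_log_or <= res.ci95[1]

    def test_invariant_under_stratum_replication(self):
        t = GeneCountTable("g", 60, 40, 50.0, 50.0)
        one = meta_ami([t]).pooled_log_or
        many = meta_ami([t] * 4).pooled_log_or
        assert many == pytest.approx(one, abs=1e-12)

    @given(
        st.lists(
            st.tuples(*[st.integers(1, 30)] * 4), min_size=1, max_size=5
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_pooled_or_matches_rational_oracle(self, cells):
        log_or, se = _mh_log_or_se(np.array(cells, dtype=float))
        assert log_or == pytest.approx(float(math.log(mh_oracle(cells))), abs=1e-9)
        assert se > 0

    def test_expected_cells_enter_unrounded(self):
        t = GeneCountTable("g", 7, 3, 6.25, 3.75)
        expected = math.log((7 * 3.75) / (3 * 6.25))
        assert meta_ami([t]).pooled_log_or == pytest.approx(expected, abs=1e-12)

    def test_empty_phenotype_is_error(self):
        with pytest.raises(ValueError, match="empty phenotype"):
            meta_ami([])

    def test_all_zero_hom_uses_continuity_in_pooling(self):
        tables = [GeneCountTable(f"g{i}", 0, 10, 5.0, 5.0) for i in range(3)]
        res = meta_ami(tables)
        assert math.isfinite(res.pooled_log_or) and res.pooled_log_or < 0


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_qvalues([0.01]) == pytest.approx([0.01])

    def test_hand_computed_stepup(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_qvalues([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_empty(self):
        assert bh_qvalues([]).size == 0


class TestDistributionComparison:
    def test_identical_lists(self):
        assert compare_ami_distributions([0.1, 0.1], [0.1, 0.1]) == (0.0, 1.0)

    def test_separated_distributions(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(0.11, 0.14, size=10_000)
        exp = rng.normal(-0.01, 0.03, size=10_000)
        t, p = compare_ami_distributions(obs, exp)
        assert t > 0 and p < 1e-10

    def test_argument_order_antisymmetry(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 100).tolist()
        b = rng.normal(1, 1, 100).tolist()
        t1, p1 = compare_ami_distributions(a, b)
        t2, p2 = compare_ami_distributions(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestCrossPopulationVariance:
    def test_identical_across_populations_is_zero(self):
        df = pd.DataFrame({"p1": [0.2, 0.4], "p2": [0.2, 0.4]},
                          index=["a", "b"])
        recs = ami_cross_population_variance(df)
        assert recs[0].raw_variance == 0.0

    def test_single_phenotype_normalizes_to_one(self):
        df = pd.DataFrame({"p1": [0.1], "p2": [0.5]}, index=["a"])
        (rec,) = ami_cross_population_variance(df)
        assert rec.normalized_variance == pytest.approx(1.0)

    def test_hand_computed_normalization(self):
        # variances 0.02, 0.04, 0.06 -> normalized 0.5, 1.0, 1.5
        df = pd.DataFrame(
            {"p1": [0.0, 0.0, 0.0], "p2": [0.2, 0.28284271247461906, 0.3464101615137755]},
            index=["a", "b", "c"],
        )
        recs = ami_cross_population_variance(df)
        assert [r.raw_variance for r in recs] == pytest.approx([0.02, 0.04, 0.06])
        assert [r.normalized_variance for r in recs] == pytest.approx([0.5, 1.0, 1.5])

    def test_empirical_p_from_null_draws(self):
        df = pd.DataFrame({"p1": [0.0, 0.0], "p2": [1.0, 0.01]}, index=["a", "b"])
        null = {"a": np.full(99, 1e-4), "b": np.full(99, 1e-4)}
        recs = ami_cross_population_variance(df, null)
        assert recs[0].p_value == pytest.approx(2 / 100)  # extreme high variance
        assert recs[0].q_value <= 1.0
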