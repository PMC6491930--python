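import numpy as np
import pytest

from amix.ancestry_io import (
    AncestryGenotypeMatrix,
    AncestrySegment,
    GeneAnnotation,
    ParseError,
    ValidationError,
    apply_ancestry_genotype_threshold,
    call_gene_ancestry_genotypes,
    read_ancestry_segments,
    read_gene_annotations,
    write_ancestry_segments,
)
from conftest import make_matrix


def brute_force_call(segments, genes, min_certainty):
    """Independent oracle: scan all (gene, segment) pairs for containment."""
    individuals = sorted({s.individual_id for s in segments})
    out = {}
    for g in genes:
        for ind in individuals:
            labels = []
            for hap in (0, 1):
                label = None
                for s in segments:
                    if (s.individual_id == ind and s.haplotype_index == hap
                            and s.chrom == g.chrom and s.certainty >= min_certainty
                            and s.start <= g.start and s.end >= g.end):
                        label = s.ancestry
                labels.append(label)
            out[(g.gene_id, ind)] = tuple(sorted(x for x in labels if x))
    return out


def matrix_cells(matrix):
    from amix.ancestry_io import ANCESTRIES

    out = {}
    for gi, gid in enumerate(matrix.genes):
        for ni, ind in enumerate(matrix.individuals):
            pair = tuple(
                ANCESTRIES[c] for c in matrix.haps[gi, ni] if c >= 0
            )
            out[(gid, ind)] = tuple(sorted(pair))
    return out


class TestSegmentIO:
    def test_segment_tsv_row_maps_fields(self, tmp_path):
        p = tmp_path / "segs.tsv"
        p.write_text("#header\nind1\t0\tchr1\t1000\t5000\tAFR\t0.995\n")
        (seg,) = read_ancestry_segments(p)
        assert seg == AncestrySegment("ind1", 0, "chr1", 1000, 5000, "AFR", 0.995)

    def test_empty_file_gives_empty_set(self, tmp_path, caplog):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_ancestry_segments(p) == []
        assert "no segments" in caplog.text

    def test_abutting_half_open_segments_accepted(self, tmp_path):
        p = tmp_path / "abut.tsv"
        p.write_text(
            "ind1\t0\tchr1\t0\t100\tAFR\t1.0\n"
            "ind1\t0\tchr1\t100\t200\tEUR\t1.0\n"
        )
        segs = read_ancestry_segments(p)
        assert len(segs) == 2
        # interval-overlap oracle: count overlapping ordered pairs
        overlaps = sum(
            1
            for a in segs
            for b in segs
            if a is not b and a.start < b.end and b.start < a.end
        )
        assert overlaps == 0

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "overlap.tsv"
        p.write_text(
            "ind1\t0\tchr1\t0\t150\tAFR\t1.0\n"
            "ind1\t0\tchr1\t100\t200\tEUR\t1.0\n"
        )
        with pytest.raises(ValidationError, match="overlap"):
            read_ancestry_segments(p)

    def test_unknown_ancestry_label_named_with_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("ind1\t0\tchr1\t0\t100\tASN\t1.0\n")
        with pytest.raises(ParseError, match=r"bad.tsv:1.*ASN"):
            read_ancestry_segments(p)

    def test_write_read_round_trip(self, toy_segments, tmp_path):
        p = tmp_path / "rt.tsv"
        write_ancestry_segments(toy_segments, p)
        back = read_ancestry_segments(p)
        assert sorted(back, key=str) == sorted(toy_segments, key=str)

    def test_rfmix_v1_runs_collapse_to_segments(self, tmp_path):
        # 4 markers, 1 individual (2 haplotype columns); hap0 switches AFR->EUR
        viterbi = tmp_path / "v.Viterbi.txt"
        viterbi.write_text("1 2\n1 2\n2 2\n2 2\n")
        pos = tmp_path / "pos.txt"
        pos.write_text("#chrom=chr9\n101\n201\n301\n401\n")
        segs = read_ancestry_segments(viterbi, "rfmix_v1", positions_path=pos)
        hap0 = sorted(
            [s for s in segs if s.haplotype_index == 0], key=lambda s: s.start
        )
        assert [(s.start, s.end, s.ancestry) for s in hap0] == [
            (100, 201, "AFR"),
            (300, 401, "EUR"),
        ]
        (hap1,) = [s for s in segs if s.haplotype_index == 1]
        assert (hap1.start, hap1.end, hap1.ancestry, hap1.chrom) == (
            100, 401, "EUR", "chr9",
        )

    def test_rfmix_v1_requires_positions(self, tmp_path):
        p = tmp_path / "v.txt"
        p.write_text("1 1\n")
        with pytest.raises(ValueError, match="positions"):
            read_ancestry_segments(p, "rfmix_v1")


class TestGeneAnnotations:
    def test_bed_line_maps_fields(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t500\tGENE_A\n")
        (g,) = read_gene_annotations(p)
        assert (g.gene_id, g.chrom, g.start, g.end) == ("GENE_A", "chr1", 100, 500)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t500\tA\nchr2\t1\t2\tA\n")
        with pytest.raises(ValidationError, match="'A'"):
            read_gene_annotations(p)

    def test_bad_interval_rejected(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t500\t500\tA\n")
        with pytest.raises(ValidationError):
            read_gene_annotations(p)

    def test_output_sorted_matches_sort_oracle(self, tmp_path):
        rows = [("chr2", 50, 60, "X"), ("chr1", 500, 900, "Y"), ("chr1", 10, 20, "Z")]
        p = tmp_path / "genes.bed"
        p.write_text("".join(f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in rows))
        got = [(g.chrom, g.start) for g in read_gene_annotations(p)]
        assert got == sorted((c, s) for c, s, _, _ in rows)

    def test_sex_chromosomes_excluded(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chrX\t1\t10\tA\nchr1\t1\t10\tB\n")
        assert [g.gene_id for g in read_gene_annotations(p)] == ["B"]


class TestGenotypeCalling:
    def test_full_containment_both_haplotypes(self, toy_segments, toy_genes):
        m = call_gene_ancestry_genotypes(toy_segments, toy_genes, 0.99)
        cells = matrix_cells(m)
        # GENE_A inside AFR (hap0, 0.999) and EUR (hap1, 0.995) for ind1
        assert cells[("GENE_A", "ind1")] == ("AFR", "EUR")

    def test_boundary_spanning_gene_gets_single_label(self, toy_segments, toy_genes):
        m = call_gene_ancestry_genotypes(toy_segments, toy_genes, 0.99)
        # GENE_B [3500,4500) straddles ind1's hap1 EUR/NAT switch at 4000
        assert matrix_cells(m)[("GENE_B", "ind1")] == ("AFR",)

    def test_low_certainty_segment_excluded(self, toy_segments, toy_genes):
        m = call_gene_ancestry_genotypes(toy_segments, toy_genes, 0.99)
        # ind2 hap0 certainty 0.98 < 0.99: single EUR from hap1 everywhere
        for gid in ("GENE_A", "GENE_B", "GENE_C"):
            assert matrix_cells(m)[(gid, "ind2")] == ("EUR",)

    def test_matches_brute_force_oracle(self, toy_segments, toy_genes):
        m = call_gene_ancestry_genotypes(toy_segments, toy_genes, 0.99)
        assert matrix_cells(m) == brute_force_call(toy_segments, toy_genes, 0.99)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_genes = rng.integers(1, 10)
            n_ind = rng.integers(1, 5)
            segments = []
            for i in range(n_ind):
                for hap in (0, 1):
                    pos = 0
                    while pos < 5000 and rng.random() < 0.9:
                        end = pos + int(rng.integers(200, 2000))
                        segments.append(
                            AncestrySegment(
                                f"i{i}", hap, "chr1", pos, end,
                                ["AFR", "EUR", "NAT"][rng.integers(3)],
                                float(rng.choice([0.95, 0.992, 1.0])),
                            )
                        )
                        pos = end
            genes = [
                GeneAnnotation(f"g{k}", "chr1", int(s), int(s) + 300)
                for k, s in enumerate(rng.integers(0, 5000, size=n_genes))
            ]
            m = call_gene_ancestry_genotypes(segments, genes, 0.99)
            assert matrix_cells(m) == brute_force_call(segments, genes, 0.99)

    def test_absent_chromosome_gives_missing_column(self, toy_segments):
        genes = [GeneAnnotation("G_OFF", "chr7", 0, 100)]
        m = call_gene_ancestry_genotypes(toy_segments, genes, 0.99)
        assert all(v == () for v in matrix_cells(m).values())

    def test_negative_certainty_rejected(self, toy_segments, toy_genes):
        with pytest.raises(ValueError):
            call_gene_ancestry_genotypes(toy_segments, toy_genes, -0.1)

    def test_raising_certainty_never_increases_counts(self, toy_segments, toy_genes):
        lo = call_gene_ancestry_genotypes(toy_segments, toy_genes, 0.9)
        hi = call_gene_ancestry_genotypes(toy_segments, toy_genes, 0.999)
        assert (hi.n_pairs <= lo.n_pairs).all()


class TestThreshold:
    def _matrix_with_counts(self, counts, n_ind):
        cells = []
        for c in counts:
            cells.append([("AFR", "EUR")] * c + [()] * (n_ind - c))
        return make_matrix(cells)

    def test_degenerate_sd_retains_all(self):
        m = self._matrix_with_counts([90, 90, 90], 90)
        kept, thr = apply_ancestry_genotype_threshold(m)
        assert len(kept.genes) == 3 and thr == 90.0

    def test_low_count_gene_dropped(self):
        m = self._matrix_with_counts([100, 100, 10], 100)
        kept, thr = apply_ancestry_genotype_threshold(m)
        assert kept.genes == ["G1", "G2"]
        assert thr == pytest.approx(70 - 51.96152, abs=1e-4)

    def test_single_gene_retained(self):
        m = self._matrix_with_counts([50], 50)
        kept, thr = apply_ancestry_genotype_threshold(m)
        assert kept.genes == ["G1"] and thr == 50.0

    def test_all_missing_is_error(self):
        m = make_matrix([[(), ()], [(), ()]])
        with pytest.raises(ValidationError, match="no callable genes"):
            apply_ancestry_genotype_threshold(m)


def test_matrix_tsv_round_trip(tmp_path):
    m = make_matrix(
        [[("AFR", "EUR"), ("NAT", "NAT")], [("EUR",), ()]], population_id="px"
    )
    p = tmp_path / "px.tsv"
    m.to_tsv(p)
    back = AncestryGenotypeMatrix.from_tsv(p)
    assert back.population_id == "px"
    assert back.genes == m.genes and back.individuals == m.individuals
    assert (back.haps == m.haps).all()


def test_unordered_pair_normalization():
    a = make_matrix([[("AFR", "EUR")]])
    b = make_matrix([[("EUR", "AFR")]])
    assert (a.haps == b.haps).all()
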