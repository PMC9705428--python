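"""Interval algebra, BED I/O, peak annotation and motif allele scoring."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regulink.genomic import (
    PWM,
    AnnotationResult,
    GeneModel,
    GenomicInterval,
    PeakSet,
    annotate_peaks_to_genes,
    cooccupancy_fraction,
    merge_intervals,
    partition_peak_sets,
    pwm_allele_delta,
    read_bed,
    write_bed,
)
from conftest import coverage_mask, random_peakset


def ps(*ivs, name="p"):
    return PeakSet(name, pd.DataFrame(list(ivs), columns=["chrom", "start", "end"]))


class TestBedIO:
    def test_single_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrS\t0\t100\n")
        peaks = read_bed(p)
        assert peaks.df.iloc[0].tolist() == ["chrS", 0, 100]

    def test_roundtrip(self, tmp_path):
        peaks = ps(("chrS", 0, 100), ("chrS", 200, 350), ("chr2", 5, 10))
        out = write_bed(peaks, tmp_path / "b.bed")
        assert read_bed(out) == peaks

    def test_comments_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("# a comment\ntrack name=x\nchrS\t10\t20\n")
        assert len(read_bed(p)) == 1

    def test_malformed_line_cites_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chrS\t100\t50\n")
        with pytest.raises(ValueError, match=":1:"):
            read_bed(p)

    def test_negative_coordinates_rejected(self, tmp_path):
        p = tmp_path / "neg.bed"
        p.write_text("chrS\t5\t9\nchrS\t-1\t5\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bed(p)


class TestMerge:
    @pytest.mark.parametrize(
        "inp,expected",
        [
            ([(0, 10), (5, 20)], [(0, 20)]),
            ([(0, 5), (5, 9)], [(0, 9)]),  # touching intervals coalesce
            ([(0, 3), (10, 12)], [(0, 3), (10, 12)]),
        ],
    )
    def test_merge_examples(self, inp, expected):
        merged = merge_intervals(ps(*[("chrS", s, e) for s, e in inp]))
        assert [(r.start, r.end) for r in merged.df.itertuples()] == expected

    def test_covered_bases_preserved_vs_per_base_oracle(self, rng):
        for _ in range(30):
            peaks = random_peakset(rng, n=100)
            merged = merge_intervals(peaks)
            assert merged.total_span == int(coverage_mask(peaks).sum())
            assert merged.is_normalized()

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=30))
    def test_merge_idempotent(self, raw):
        peaks = ps(*[("chrS", s, s + l) for s, l in raw])
        once = merge_intervals(peaks)
        assert merge_intervals(once) == once


class TestPartition:
    def test_geometry_example(self):
        ua, common, ub = partition_peak_sets(ps(("chrS", 0, 100)), ps(("chrS", 50, 150)))
        assert [(r.start, r.end) for r in ua.df.itertuples()] == [(0, 50)]
        assert [(r.start, r.end) for r in common.df.itertuples()] == [(50, 100)]
        assert [(r.start, r.end) for r in ub.df.itertuples()] == [(100, 150)]

    def test_identical_sets(self):
        a = ps(("chrS", 5, 50), ("chrS", 80, 99)).normalize()
        ua, common, ub = partition_peak_sets(a, a)
        assert len(ua) == 0 and len(ub) == 0
        assert common == a

    def test_disjoint_and_base_conserving_vs_per_base_oracle(self, rng):
        for _ in range(50):
            a = random_peakset(rng, "a").normalize()
            b = random_peakset(rng, "b").normalize()
            ua, common, ub = partition_peak_sets(a, b)
            ma, mb = coverage_mask(a), coverage_mask(b)
            assert (coverage_mask(ua) == (ma & ~mb)).all()
            assert (coverage_mask(common) == (ma & mb)).all()
            assert (coverage_mask(ub) == (mb & ~ma)).all()
            # pairwise disjoint, union of bases preserved
            assert ua.total_span + common.total_span + ub.total_span == int((ma | mb).sum())


class TestCooccupancy:
    def test_single_overlap(self):
        assert tuple(cooccupancy_fraction(ps(("chrS", 100, 200)), ps(("chrS", 150, 160)))) == (1, 1, 1.0)

    def test_half(self):
        a = ps(("chrS", 0, 10), ("chrS", 100, 110))
        assert cooccupancy_fraction(a, ps(("chrS", 5, 8))).fraction == 0.5

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cooccupancy_fraction(PeakSet("a", pd.DataFrame(columns=["chrom", "start", "end"])), ps(("chrS", 0, 5)))

    def test_matches_brute_force_and_is_asymmetric(self, rng):
        for _ in range(20):
            a = random_peakset(rng, "a").normalize()
            b = random_peakset(rng, "b").normalize()
            res = cooccupancy_fraction(a, b)
            brute = sum(
                any(ra.start < rb.end and rb.start < ra.end for rb in b.df.itertuples())
                for ra in a.df.itertuples()
            )
            assert res.n_cooccupied == brute
            # both directions agree with their own brute-force scan
            res_ba = cooccupancy_fraction(b, a)
            brute_ba = sum(
                any(rb.start < ra.end and ra.start < rb.end for ra in a.df.itertuples())
                for rb in b.df.itertuples()
            )
            assert res_ba.n_cooccupied == brute_ba


class TestAnnotation:
    GENES = [
        GeneModel("g900", "G900", "chrS", 900),
        GeneModel("g1200", "G1200", "chrS", 1200),
    ]

    def test_gene_at_midpoint_assigned(self):
        genes = [GeneModel("g", "G", "chrS", 1051)]  # 1-based TSS = 0-based 1050
        res = annotate_peaks_to_genes(ps(("chrS", 1000, 1100)), genes, max_distance=100_000)
        assert res.genes == {"g"}

    def test_beyond_max_distance_unassigned(self):
        genes = [GeneModel("g", "G", "chrS", 500_000)]
        res = annotate_peaks_to_genes(ps(("chrS", 0, 100)), genes, max_distance=1000)
        assert res.genes == set() and res.n_unassigned == 1

    def test_equidistant_tie_breaks_to_lower_coordinate(self):
        # peak midpoint 1050 (0-based); TSSs at 0-based 900 and 1200 are equidistant
        genes = [GeneModel("hi", "HI", "chrS", 1201), GeneModel("lo", "LO", "chrS", 901)]
        res = annotate_peaks_to_genes(ps(("chrS", 1000, 1100)), genes, max_distance=10_000)
        assert res.genes == {"lo"}

    def test_matches_exhaustive_distance_table(self, rng):
        genes = [GeneModel(f"g{i}", f"G{i}", "chrS", int(t)) for i, t in
                 enumerate(sorted(rng.integers(1, 2000, size=15)))]
        peaks = random_peakset(rng, n=30, genome=2000)
        res = annotate_peaks_to_genes(peaks, genes, max_distance=300)
        expected = set()
        for r in peaks.df.itertuples():
            mid = (r.start + r.end) / 2
            dists = sorted(((abs(mid - (g.tss - 1)), g.tss, g.gene_id) for g in genes))
            if dists[0][0] <= 300:
                expected.add(dists[0][2])
        assert res.genes == expected


class TestPWM:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(np.full((4, 3), 0.25))
        res = pwm_allele_delta(pwm, "ACGTACG", 3, "T", "G")
        # log2((0.25 + pseudocount)/0.25) per position, identical for every window
        per_base = np.log2((0.25 + PWM.PSEUDOCOUNT) / 0.25)
        assert res.best_ref_score == pytest.approx(3 * per_base)
        assert res.delta == pytest.approx(0.0)

    def test_ref_equals_alt_gives_zero_delta(self):
        pwm = PWM.from_counts(np.array([[8, 2], [1, 1], [1, 6], [2, 3]]))
        res = pwm_allele_delta(pwm, "AACGT", 2, "C", "C")
        assert res.delta == 0.0

    def test_wrong_ref_base_rejected(self):
        pwm = PWM(np.full((4, 2), 0.25))
        with pytest.raises(ValueError, match="expected ref"):
            pwm_allele_delta(pwm, "ACGT", 1, "G", "T")

    def test_matches_brute_force_enumeration(self):
        m = np.array([[0.7, 0.1], [0.1, 0.2], [0.1, 0.6], [0.1, 0.1]])
        pwm = PWM(m)
        seq, off, ref, alt = "TAGC", 2, "G", "A"
        res = pwm_allele_delta(pwm, seq, off, ref, alt)

        def score(win):  # independent re-implementation
            lo = np.log2((m + PWM.PSEUDOCOUNT) / 0.25)
            idx = ["ACGT".index(b) for b in win]
            return lo[idx[0], 0] + lo[idx[1], 1]

        def rc(s):
            return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

        def best(s):
            wins = [s[i:i + 2] for i in range(len(s) - 1) if i <= off <= i + 1]
            return max(max(score(w), score(rc(w))) for w in wins)

        alt_seq = seq[:off] + alt + seq[off + 1:]
        assert res.best_ref_score == pytest.approx(best(seq), abs=1e-12)
        assert res.best_alt_score == pytest.approx(best(alt_seq), abs=1e-12)

    def test_strand_symmetry(self, rng):
        m = rng.dirichlet(np.ones(4), size=5).T
        pwm = PWM(m)
        seq = "".join(rng.choice(list("ACGT"), size=20))
        off = 10
        res = pwm_allele_delta(pwm, seq, off, seq[off], "A" if seq[off] != "A" else "C")
        rc_seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        rc_off = len(seq) - 1 - off
        res_rc = pwm_allele_delta(
            pwm, rc_seq, rc_off, rc_seq[rc_off],
            ("A" if seq[off] != "A" else "C").translate(str.maketrans("ACGT", "TGCA")),
        )
        assert res.best_ref_score == pytest.approx(res_rc.best_ref_score)
        assert res.delta == pytest.approx(res_rc.delta)

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chrS", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)
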