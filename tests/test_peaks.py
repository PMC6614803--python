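import math

import numpy as np
import pytest

from pixulchip.errors import ConfigurationError, FormatError, ValidationError
from pixulchip.peaks import (
    DEFAULT_FILTER_RULES,
    ExpressionStrata,
    FilterRule,
    Peak,
    TSSRecord,
    assign_tss_marks,
    expression_strata,
    filter_peaks,
    overlap_fraction,
    read_broadpeak,
    read_tss_bed,
    write_broadpeak,
)


def random_peaks(rng, n, chroms=("chr1", "chr2", "chr3"), span=100_000, mark="X"):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, 2000))
        out.append(
            Peak(
                chrom=str(rng.choice(list(chroms))),
                start=start,
                end=end,
                name=f"p{i}",
                fold_enrichment=float(rng.uniform(0, 20)),
                neg_log10_q=float(rng.uniform(0, 30)),
                neg_log10_p=float(rng.uniform(0, 30)),
                mark=mark,
            )
        )
    return out


class TestBroadPeakIO:
    def test_three_line_fixture(self, tmp_path):
        path = tmp_path / "x.broadPeak"
        path.write_text(
            "chr1\t100\t500\tpeak1\t800\t.\t4.5\t10.2\t8.8\n"
            "chr2\t0\t50\tpeak2\t10\t+\t1.5\t2.0\t1.1\n"
            "chr10\t7\t9\tpeak3\t0\t-\t0.0\t0.0\t0.0\n"
        )
        peaks = read_broadpeak(str(path), mark="H3K4m3")
        assert len(peaks) == 3
        assert peaks[0].chrom == "chr1"
        assert (peaks[0].start, peaks[0].end) == (100, 500)
        assert peaks[0].fold_enrichment == 4.5
        assert peaks[0].neg_log10_q == 8.8
        assert peaks[1].strand == "+"
        assert all(p.mark == "H3K4m3" for p in peaks)

    def test_end_not_after_start_names_line(self, tmp_path):
        path = tmp_path / "x.broadPeak"
        path.write_text(
            "chr1\t100\t500\tpeak1\t800\t.\t4.5\t10.2\t8.8\n"
            "chr1\t600\t600\tpeak2\t800\t.\t4.5\t10.2\t8.8\n"
        )
        with pytest.raises(FormatError, match=":2"):
            read_broadpeak(str(path))

    def test_too_few_columns_names_line(self, tmp_path):
        path = tmp_path / "x.broadPeak"
        path.write_text("chr1\t100\t500\tpeak1\t800\t.\t4.5\n")
        with pytest.raises(FormatError, match=":1"):
            read_broadpeak(str(path))

    def test_roundtrip_1000_random_peaks(self, tmp_path):
        rng = np.random.default_rng(0)
        peaks = random_peaks(rng, 1000, mark="")
        path = tmp_path / "rt.broadPeak"
        write_broadpeak(peaks, str(path))
        back = read_broadpeak(str(path))
        assert back == peaks

    def test_track_and_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "x.broadPeak"
        path.write_text(
            "track name=peaks\n# comment\n\nchr1\t1\t2\tp\t0\t.\t1.0\t1.0\t1.0\n"
        )
        assert len(read_broadpeak(str(path))) == 1


class TestFilterPeaks:
    def _peak(self, mark, neg_q, fold):
        return Peak(
            chrom="chr1", start=0, end=100,
            fold_enrichment=fold, neg_log10_q=neg_q, mark=mark,
        )

    def test_relaxed_mark_kept(self):
        # H3K4m1 rule: q < 1e-3 (neg_log10_q > 3) and fold > 2
        kept = filter_peaks([self._peak("H3K4m1", 3.5, 2.5)])
        assert len(kept) == 1

    def test_stringent_mark_on_boundary_removed(self):
        # default rule: q < 1e-10 and fold > 5; 9.9 fails
        kept = filter_peaks([self._peak("H3K4m3", 9.9, 10.0)])
        assert kept == []

    def test_strict_inequalities_at_thresholds(self):
        assert filter_peaks([self._peak("H3K4m1", 3.0, 2.5)]) == []
        assert filter_peaks([self._peak("H3K4m1", 3.5, 2.0)]) == []
        assert filter_peaks([self._peak("H3K4m3", 10.0, 6.0)]) == []
        assert len(filter_peaks([self._peak("H3K4m3", 10.0001, 5.0001)])) == 1

    def test_matches_per_record_oracle_on_random_peaks(self):
        rng = np.random.default_rng(1)
        marks = ["H3K4m1", "H3K27m3", "H3K27Ac", "H3K4m3", "H3K9Ac", "CTCF"]
        peaks = []
        for i in range(10_000):
            peaks.append(
                Peak(
                    chrom="chr1", start=i, end=i + 10,
                    fold_enrichment=float(rng.uniform(0, 12)),
                    neg_log10_q=float(rng.uniform(0, 15)),
                    mark=str(rng.choice(marks)),
                )
            )
        kept = filter_peaks(peaks)
        relaxed = {"H3K4m1", "H3K27m3", "H3K27Ac"}
        oracle = [
            p
            for p in peaks
            if (
                (p.neg_log10_q > 3.0 and p.fold_enrichment > 2.0)
                if p.mark in relaxed
                else (p.neg_log10_q > 10.0 and p.fold_enrichment > 5.0)
            )
        ]
        assert kept == oracle

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        peaks = random_peaks(rng, 500, mark="H3K4m1")
        once = filter_peaks(peaks)
        twice = filter_peaks(once)
        assert once == twice

    def test_unmatched_mark_without_default_raises(self):
        rules = (FilterRule(q_max=1e-3, fold_min=2.0, mark_set=frozenset({"A"})),)
        with pytest.raises(ConfigurationError, match="B"):
            filter_peaks([self._peak("B", 5.0, 5.0)], rules)

    def test_rule_validation(self):
        with pytest.raises(ValidationError):
            FilterRule(q_max=1.5, fold_min=2.0)
        with pytest.raises(ValidationError):
            FilterRule(q_max=1e-3, fold_min=0.0)


class TestOverlapFraction:
    def test_self_overlap_is_100(self):
        rng = np.random.default_rng(3)
        peaks = random_peaks(rng, 200)
        res = overlap_fraction(peaks, peaks)
        assert res.percent == 100.0
        assert res.count_overlapping == len(peaks)

    def test_disjoint_chromosomes(self):
        rng = np.random.default_rng(4)
        a = random_peaks(rng, 50, chroms=("chr1",))
        b = random_peaks(rng, 50, chroms=("chr2",))
        res = overlap_fraction(a, b)
        assert res.percent == 0.0

    def test_empty_a_flagged(self):
        rng = np.random.default_rng(5)
        b = random_peaks(rng, 10)
        res = overlap_fraction([], b)
        assert math.isnan(res.percent)
        assert "undefined_percent" in res.flags

    def test_half_open_touching_intervals_do_not_overlap(self):
        a = [Peak(chrom="chr1", start=0, end=100, fold_enrichment=1, neg_log10_q=1)]
        b = [Peak(chrom="chr1", start=100, end=200, fold_enrichment=1, neg_log10_q=1)]
        assert overlap_fraction(a, b).count_overlapping == 0
        b2 = [Peak(chrom="chr1", start=99, end=200, fold_enrichment=1, neg_log10_q=1)]
        assert overlap_fraction(a, b2).count_overlapping == 1

    def test_matches_brute_force_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = random_peaks(rng, 500, span=50_000)
            b = random_peaks(rng, 500, span=50_000)
            res = overlap_fraction(a, b)
            brute = sum(
                1
                for pa in a
                if any(
                    pa.chrom == pb.chrom and pa.start < pb.end and pb.start < pa.end
                    for pb in b
                )
            )
            assert res.count_overlapping == brute
            assert res.count_a == len(a)

    def test_merging_b_does_not_change_counts(self):
        rng = np.random.default_rng(77)
        a = random_peaks(rng, 300, span=20_000)
        b = random_peaks(rng, 300, span=20_000)
        res = overlap_fraction(a, b)
        # merge b manually into disjoint intervals
        by_chrom = {}
        for p in sorted(b, key=lambda p: (p.chrom, p.start)):
            ivs = by_chrom.setdefault(p.chrom, [])
            if ivs and p.start <= ivs[-1][1]:
                ivs[-1][1] = max(ivs[-1][1], p.end)
            else:
                ivs.append([p.start, p.end])
        merged = [
            Peak(chrom=c, start=s, end=e, fold_enrichment=1, neg_log10_q=1)
            for c, ivs in by_chrom.items()
            for s, e in ivs
        ]
        res_m = overlap_fraction(a, merged)
        assert res.count_overlapping == res_m.count_overlapping


class TestAssignTssMarks:
    def _peak(self, start, end, chrom="chr1"):
        return Peak(chrom=chrom, start=start, end=end, fold_enrichment=1, neg_log10_q=1)

    def test_peak_covering_tss_flagged(self):
        tss = [TSSRecord(gene_id="g1", chrom="chr1", tss=5000)]
        flags = assign_tss_marks([self._peak(4990, 5010)], tss, window=2000)
        assert flags == {"g1": True}

    def test_peak_just_outside_window_not_flagged(self):
        tss = [TSSRecord(gene_id="g1", chrom="chr1", tss=5000)]
        # window [3000, 7000); peak ending at 2999 shares no base
        flags = assign_tss_marks([self._peak(2000, 2999)], tss, window=2000)
        assert flags == {"g1": False}
        # ending exactly at the window start is still outside (half-open)
        flags = assign_tss_marks([self._peak(2000, 3000)], tss, window=2000)
        assert flags == {"g1": False}
        flags = assign_tss_marks([self._peak(2000, 3001)], tss, window=2000)
        assert flags == {"g1": True}

    def test_gene_body_mode(self):
        tss = [TSSRecord(gene_id="g1", chrom="chr1", tss=5000)]
        spans = {"g1": ("chr1", 5000, 20_000)}
        peak = self._peak(15_000, 15_500)  # far from TSS window, inside body
        assert assign_tss_marks([peak], tss, window=2000) == {"g1": False}
        flags = assign_tss_marks(
            [peak], tss, window=2000, include_gene_body=True, gene_spans=spans
        )
        assert flags == {"g1": True}

    def test_gene_body_requires_spans(self):
        tss = [TSSRecord(gene_id="g1", chrom="chr1", tss=5000)]
        with pytest.raises(ConfigurationError):
            assign_tss_marks([], tss, include_gene_body=True)
        with pytest.raises(ConfigurationError, match="g1"):
            assign_tss_marks(
                [self._peak(0, 1)], tss, include_gene_body=True, gene_spans={}
            )

    def test_matches_brute_force_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            peaks = random_peaks(rng, 200, span=200_000)
            tss = [
                TSSRecord(
                    gene_id=f"g{i}",
                    chrom=str(rng.choice(["chr1", "chr2", "chr3"])),
                    tss=int(rng.integers(0, 200_000)),
                )
                for i in range(200)
            ]
            window = 1500
            flags = assign_tss_marks(peaks, tss, window=window)
            for rec in tss:
                lo, hi = max(0, rec.tss - window), rec.tss + window
                expected = any(
                    p.chrom == rec.chrom and p.start < hi and lo < p.end for p in peaks
                )
                assert flags[rec.gene_id] == expected


class TestExpressionStrata:
    def test_all_genes_flagged(self):
        strata = expression_strata({"g1": True, "g2": True}, [("g1", 5.0), ("g2", 7.0)])
        assert strata.without_mark == []
        assert strata.summary["with_mark"]["n"] == 2
        assert strata.summary["without_mark"]["n"] == 0

    def test_two_point_case(self):
        strata = expression_strata(
            {"hi": True, "lo": False}, [("hi", 32.0), ("lo", 0.5)]
        )
        assert strata.summary["with_mark"]["mean_fpkm"] == pytest.approx(32.0)
        assert strata.summary["without_mark"]["mean_fpkm"] == pytest.approx(0.5)
        assert strata.summary["with_mark"]["mean_log2"] == pytest.approx(np.log2(33.0))

    def test_unflagged_genes_default_to_without(self):
        strata = expression_strata({}, [("g1", 1.0)])
        assert strata.with_mark == []
        assert strata.without_mark == [("g1", 1.0)]

    def test_bimodal_cohort_recovery(self):
        # flagged genes ~ LN around 32 FPKM, unflagged ~ LN around 0.5
        rng = np.random.default_rng(9)
        n = 2000
        flagged = {f"a{i}": True for i in range(n)}
        flagged.update({f"b{i}": False for i in range(n)})
        expr = [(f"a{i}", float(32.0 * np.exp(rng.normal(0, 0.4)))) for i in range(n)]
        expr += [(f"b{i}", float(0.5 * np.exp(rng.normal(0, 0.4)))) for i in range(n)]
        strata = expression_strata(flagged, expr)
        gen_mean_hi = 32.0 * np.exp(0.4**2 / 2)
        gen_mean_lo = 0.5 * np.exp(0.4**2 / 2)
        assert strata.summary["with_mark"]["mean_fpkm"] == pytest.approx(gen_mean_hi, rel=0.1)
        assert strata.summary["without_mark"]["mean_fpkm"] == pytest.approx(gen_mean_lo, rel=0.1)

    def test_empty_expression_rejected(self):
        with pytest.raises(ValidationError):
            expression_strata({}, [])

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(10)
        expr = [(f"g{i}", float(rng.uniform(0, 50))) for i in range(100)]
        flags = {f"g{i}": bool(rng.integers(0, 2)) for i in range(100)}
        strata = expression_strata(flags, expr)
        ids = [g for g, _ in strata.with_mark] + [g for g, _ in strata.without_mark]
        assert sorted(ids) == sorted(g for g, _ in expr)
        assert isinstance(strata, ExpressionStrata)


def test_read_tss_bed_strand_handling(tmp_path):
    path = tmp_path / "tss.bed"
    path.write_text(
        "chr1\t1000\t2000\tgenePlus\t0\t+\n"
        "chr1\t3000\t4000\tgeneMinus\t0\t-\n"
    )
    records = read_tss_bed(str(path))
    assert records[0].tss == 1000
    assert records[1].tss == 3999
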