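"""ATAC peak scoring: normalization, promoter windows, MA summaries."""

import numpy as np
import pandas as pd
import pytest

from senprof.atac import (
    PeakTable,
    differential_peaks,
    group_average_promoters,
    ma_summary,
    normalize_peaks,
)


def make_peaks(rows, counts, groups=None):
    meta = pd.DataFrame(rows).set_index("peak_id")
    counts = pd.DataFrame(counts, index=meta.index)
    if groups is None:
        groups = pd.Series({s: s.split("_")[0] for s in counts.columns})
    return PeakTable(meta, counts, groups)


class TestNormalizePeaks:
    def test_hand_example(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["p1", "p2"])
        lengths = pd.Series([1000, 2000], index=["p1", "p2"])
        # rpk = 10, 5 -> scores 2:1 summing to 1e6
        out = normalize_peaks(counts, lengths)
        assert out["s"].tolist() == pytest.approx([666666.6667, 333333.3333], rel=1e-8)

    def test_single_peak(self):
        out = normalize_peaks(
            pd.DataFrame({"s": [7]}, index=["p"]), pd.Series([500], index=["p"])
        )
        assert out.loc["p", "s"] == pytest.approx(1e6)

    def test_scale_invariance_and_conservation(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 50, size=(20, 3)))
        lengths = pd.Series(rng.integers(200, 2000, size=20))
        a = normalize_peaks(counts, lengths)
        b = normalize_peaks(counts * 3, lengths)
        assert np.allclose(a, b)
        assert np.allclose(a.sum(axis=0), 1e6)


def promoter_fixture():
    tss = 10_000
    rows = [
        # peak covering the TSS
        {"peak_id": "at_tss", "chrom": "chr1", "start": tss - 100, "end": tss + 100,
         "annotation": "promoter-TSS", "gene": "g", "tss": tss},
        # nearest covered base at TSS+999 -> inside the window
        {"peak_id": "edge_in", "chrom": "chr1", "start": tss + 999, "end": tss + 1200,
         "annotation": "promoter-TSS", "gene": "g", "tss": tss},
        # nearest covered base at TSS+1001 -> outside
        {"peak_id": "edge_out", "chrom": "chr1", "start": tss + 1001, "end": tss + 1300,
         "annotation": "promoter-TSS", "gene": "g", "tss": tss},
        # inside the window but not promoter-annotated
        {"peak_id": "distal", "chrom": "chr1", "start": tss - 50, "end": tss + 50,
         "annotation": "intergenic", "gene": "", "tss": np.nan},
    ]
    counts = {
        "Sen_1": [10, 20, 30, 40],
        "Sen_2": [12, 22, 32, 42],
        "NSen_1": [11, 21, 31, 41],
        "NSen_2": [9, 19, 29, 39],
    }
    return make_peaks(rows, counts)


class TestPromoterSelection:
    def test_boundary_peaks(self):
        out = group_average_promoters(promoter_fixture())
        assert set(out.index) == {"at_tss", "edge_in"}

    def test_non_promoter_never_selected(self):
        out = group_average_promoters(promoter_fixture())
        assert "distal" not in out.index

    def test_single_sample_group_is_identity(self):
        peaks = promoter_fixture()
        sub = PeakTable(
            peaks.meta,
            peaks.counts[["Sen_1"]],
            pd.Series({"Sen_1": "Sen"}),
        )
        out = group_average_promoters(sub, groups=["Sen"])
        norm = sub.normalized()
        assert out["Sen"].tolist() == pytest.approx(
            norm.loc[out.index, "Sen_1"].tolist()
        )

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            group_average_promoters(promoter_fixture(), groups=["Missing"])

    def test_randomized_brute_force_window_check(self):
        rng = np.random.default_rng(3)
        tss_positions = rng.integers(5_000, 50_000, size=30)
        rows = []
        for i, tss in enumerate(tss_positions):
            start = int(tss + rng.integers(-2000, 2000))
            rows.append(
                {
                    "peak_id": f"p{i}",
                    "chrom": "chr1",
                    "start": start,
                    "end": start + 300,
                    "annotation": "promoter-TSS",
                    "gene": f"g{i}",
                    "tss": int(tss),
                }
            )
        counts = {"Sen_1": [5] * 30, "Sen_2": [6] * 30, "NSen_1": [5] * 30, "NSen_2": [7] * 30}
        peaks = make_peaks(rows, counts)
        out = group_average_promoters(peaks, tss_halfwidth=1000)
        expected = {
            r["peak_id"]
            for r in rows
            if any(
                abs(pos - r["tss"]) <= 1000 for pos in range(r["start"], r["end"])
            )
        }
        assert set(out.index) == expected


class TestMASummary:
    def test_identical_groups_zero(self):
        scores = pd.DataFrame({"A": [10.0, 20.0], "B": [10.0, 20.0]})
        table, n_up, n_down = ma_summary(scores, "A", "B")
        assert (table["M"] == 0).all() and n_up == 0 and n_down == 0

    def test_strict_signal_filter(self):
        scores = pd.DataFrame(
            {"A": [4.9, 5.1, 4.0], "B": [4.9, 5.1, 6.1]},
            index=["excluded", "kept", "kept2"],
        )
        table, _, _ = ma_summary(scores, "A", "B", min_signal=5.0)
        # mean of means: 4.9 (out), 5.1 (in), 5.05 (in)
        assert set(table.index) == {"kept", "kept2"}

    def test_counts_both_directions(self):
        scores = pd.DataFrame(
            {"A": [10.0, 10.0, 10.0], "B": [50.0, 2.0, 10.0]},
        )
        _, n_up, n_down = ma_summary(scores, "A", "B")
        assert (n_up, n_down) == (1, 1)

    def test_raising_min_signal_monotone(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"A": rng.uniform(0, 20, 50), "B": rng.uniform(0, 20, 50)})
        t1, _, _ = ma_summary(scores, "A", "B", min_signal=2.0)
        t2, _, _ = ma_summary(scores, "A", "B", min_signal=8.0)
        assert set(t2.index) <= set(t1.index)


class TestDifferentialPeaks:
    def test_strict_thresholds(self):
        de = pd.DataFrame(
            {
                "log2fc": [1.5, 1.0, -1.5, -1.0, 2.0],
                "padj": [0.05, 0.05, 0.05, 0.05, 0.1],
            },
            index=["open_ok", "lfc_at_bound", "closed_ok", "neg_at_bound", "padj_at_bound"],
        )
        open_p, closed_p = differential_peaks(de, padj=0.1, lfc=1.0)
        assert open_p == {"open_ok"}
        assert closed_p == {"closed_ok"}

    def test_empty_table(self):
        de = pd.DataFrame(columns=["log2fc", "padj"])
        assert differential_peaks(de) == (set(), set())

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            differential_peaks(pd.DataFrame({"log2fc": [1.0]}))


class TestPeakTableInvariants:
    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            make_peaks(
                [{"peak_id": "p", "chrom": "c", "start": 100, "end": 100,
                  "annotation": "", "gene": "", "tss": np.nan}],
                {"s_1": [1]},
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_peaks(
                [{"peak_id": "p", "chrom": "c", "start": 0, "end": 100,
                  "annotation": "", "gene": "", "tss": np.nan}],
                {"s_1": [-1]},
            )
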