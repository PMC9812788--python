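"""Promoter chromatin-accessibility scoring from ATAC peak counts.

Peak scores are TPM-normalized read counts computed in three steps per
sample: (1) reads per kilobase = count / (peak length in kb); (2) the
per-million scaling factor = sum of all reads per kilobase in the
sample; (3) reads per kilobase divided by the scaling factor (times
1e6). Step (4) selects peaks annotated "promoter-TSS" within TSS +- 1
kb and averages per group. MA summaries filter on average normalized
signal > 5 (strict) and count peaks beyond |log2FC| > 1.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "normalize_peaks",
    "group_average_promoters",
    "ma_summary",
    "differential_peaks",
]


@dataclass
class PeakTable:
    """ATAC peaks with coordinates, annotation and per-sample counts.

    ``meta`` is indexed by peak id with columns chrom/start/end/
    annotation/gene/tss; ``counts`` shares the index with per-sample
    count columns; ``groups`` maps sample id -> group label.
    """

    meta: pd.DataFrame
    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.counts.index):
            raise ValueError("peak metadata and counts must share the peak index")
        if (self.meta["end"] <= self.meta["start"]).any():
            bad = self.meta.index[self.meta["end"] <= self.meta["start"]][0]
            raise ValueError(f"peak {bad!r} has end <= start")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("peak counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)[:5]}")

    @property
    def lengths(self) -> pd.Series:
        return self.meta["end"] - self.meta["start"]

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def normalized(self) -> pd.DataFrame:
        return normalize_peaks(self.counts, self.lengths)


def normalize_peaks(counts: pd.DataFrame, peak_lengths: pd.Series) -> pd.DataFrame:
    """TPM-style peak scores; each sample's scores sum to 1e6."""
    lengths = peak_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("peak lengths must be positive")
    rpk = counts.div(lengths / 1000.0, axis=0)
    per_sample = rpk.sum(axis=0)
    zero = per_sample.index[per_sample == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has all-zero counts")
    return rpk.div(per_sample, axis=1) * 1e6


def group_average_promoters(
    peaks: PeakTable,
    groups: list[str] | None = None,
    tss_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Per-group mean normalized score of promoter-TSS peaks.

    A peak qualifies iff it is annotated "promoter-TSS" and its nearest
    point lies within ``tss_halfwidth`` bp of the gene TSS (0-based
    half-open: positions start .. end-1).
    """
    if groups is None:
        groups = sorted(set(peaks.groups[peaks.counts.columns]))
    norm = peaks.normalized()
    meta = peaks.meta
    is_prom = meta["annotation"] == "promoter-TSS"
    tss = meta["tss"]
    # distance from the TSS to the closest base covered by the peak
    dist = np.maximum(
        meta["start"] - tss, np.maximum(tss - (meta["end"] - 1), 0)
    )
    keep = is_prom & tss.notna() & (dist <= tss_halfwidth)
    out = {}
    for grp in groups:
        samples = peaks.samples_of(grp)
        if not samples:
            raise ValueError(f"group {grp!r} has no samples")
        out[grp] = norm.loc[keep, samples].mean(axis=1)
    return pd.DataFrame(out)


def ma_summary(
    group_scores: pd.DataFrame,
    group_a: str,
    group_b: str,
    min_signal: float = 5.0,
    lfc_bound: float = 1.0,
    pseudo: float = 0.5,
) -> tuple[pd.DataFrame, int, int]:
    """MA table (A = mean signal, M = log2FC B over A) plus bound counts.

    Peaks enter only if the mean of the two group means strictly
    exceeds ``min_signal``. Returns (table, n_above, n_below) where the
    counts are peaks with M > lfc_bound and M < -lfc_bound.
    """
    a = group_scores[group_a]
    b = group_scores[group_b]
    avg = (a + b) / 2.0
    keep = avg > min_signal
    m = np.log2((b[keep] + pseudo) / (a[keep] + pseudo))
    table = pd.DataFrame({"A": avg[keep], "M": m})
    n_up = int((table["M"] > lfc_bound).sum())
    n_down = int((table["M"] < -lfc_bound).sum())
    return table, n_up, n_down


def differential_peaks(
    peak_de: pd.DataFrame, padj: float = 0.1, lfc: float = 1.0
) -> tuple[set[str], set[str]]:
    """Open/closed peak sets from a peak-level DE table (strict thresholds).

    Open = up-accessible in the senescent group (log2fc > lfc), closed
    = down-accessible; both require adjusted p strictly below ``padj``.
    """
    need = {"log2fc", "padj"}
    if not need <= set(peak_de.columns):
        raise ValueError(
            f"peak DE table missing columns {sorted(need - set(peak_de.columns))}"
        )
    sig = peak_de["padj"] < padj
    open_peaks = set(peak_de.index[sig & (peak_de["log2fc"] > lfc)])
    closed_peaks = set(peak_de.index[sig & (peak_de["log2fc"] < -lfc)])
    return open_peaks, closed_peaks
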