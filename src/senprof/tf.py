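"""Consensus transcription-factor activity, trust scoring and profiling.

Four evidence streams feed each TF's call for one Sen-vs-NSen
comparison: (1) over-representation of its regulon among DE genes,
(2) an upstream-regulator style weighted activation z-score with a
direction-bias guard, (3) the TF's own differential expression, and
(4) motif prevalence in opened versus closed chromatin. Signed-regulon
z-scores use the Ingenuity-style statistic
z = (n_consistent - n_inconsistent) / sqrt(n_total), where a target is
consistent when its DE direction matches the edge sign (up & activating
or down & inhibiting).

Calls live on a 5-level scale (inhibited, possibly inhibited,
unknown/contradictory, possibly activated, activated) and carry a 0-6
"trust" score, one point per satisfied evidence criterion; TFs with
average trust strictly above 1 across comparisons survive filtering.
Recurrently enriched TF-cluster mappings (>= 8 of 12 comparisons) are
then ranked by upper-quartile points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import DEComparison
from .stats import bh_adjust, fisher_exact_2x2, hypergeom_tail

__all__ = [
    "TFEvidence",
    "TFActivityReport",
    "STATUS_LEVELS",
    "regulon_overlap_enrichment",
    "activity_zscore",
    "upstream_regulator_z",
    "expression_zscore",
    "motif_accessibility_scores",
    "assign_activity_status",
    "trust_score",
    "filter_by_trust",
    "filter_term_size",
    "map_tf_to_clusters",
    "sasp_tf_profiling",
]

STATUS_LEVELS = (
    "inhibited",
    "possibly inhibited",
    "unknown/contradictory",
    "possibly activated",
    "activated",
)


@dataclass
class TFEvidence:
    """Assembled evidence for one TF in one comparison.

    Absent streams are ``None`` (recorded as missing, never as zero).
    """

    tf: str
    overlap_padj: float | None = None
    upstream_p: float | None = None
    upstream_z: float | None = None
    upstream_biased: bool = False
    activity_z: float | None = None
    tf_log2fc: float | None = None
    tf_padj: float | None = None
    expression_class: str = "unclear"
    accessibility_z: float | None = None
    motif_q: float | None = None


@dataclass
class TFActivityReport:
    tf: str
    comparison: str
    status: str
    trust: int
    criteria: dict[str, bool]
    evidence: TFEvidence


def regulon_overlap_enrichment(
    de: DEComparison, regulons: pd.DataFrame
) -> pd.DataFrame:
    """Hypergeometric over-representation of each regulon among DE genes.

    The query is the union of up- and down-called genes; the universe is
    every gene tested in the comparison. TFs with no target in the
    universe are skipped with a warning. BH runs across TFs.
    """
    universe = de.universe
    query = de.called_genes
    rows = []
    for tf in sorted(regulons["tf"].unique()):
        targets = set(regulons.loc[regulons["tf"] == tf, "target"]) & universe
        if not targets:
            warnings.warn(
                f"TF {tf!r} has no regulon target in the universe; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        k = len(query & targets)
        rows.append(
            {
                "tf": tf,
                "k": k,
                "K": len(targets),
                "n": len(query),
                "N": len(universe),
                "p": hypergeom_tail(k, len(targets), len(query), len(universe)),
            }
        )
    out = pd.DataFrame(rows, columns=["tf", "k", "K", "n", "N", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def _called_targets(de: DEComparison, regulon: pd.DataFrame) -> pd.DataFrame:
    """Regulon rows whose target carries a DE direction call."""
    sub = regulon.copy()
    sub["direction"] = [de.direction_of(t) for t in sub["target"]]
    return sub[sub["direction"] != 0]


def activity_zscore(de: DEComparison, regulon: pd.DataFrame) -> float | None:
    """Signed-regulon activation z; None if no target is DE-called.

    Positive z is evidence of activation: targets move the way the
    edge signs predict for an active TF.
    """
    called = _called_targets(de, regulon)
    if called.empty:
        return None
    consistent = (called["direction"] * called["sign"] > 0).sum()
    total = len(called)
    return float((2 * consistent - total) / math.sqrt(total))


def upstream_regulator_z(
    de: DEComparison, regulon: pd.DataFrame
) -> tuple[float | None, float | None, bool]:
    """Upstream-regulator stream: (overlap p, weighted activation z, bias).

    Overlap p is Fisher's exact (one-sided) of regulon targets among DE
    genes. The activation z weights each called target by its |log2FC|
    rank within the called set (w in (0, 1]):
    z = sum(w * consistency) / sqrt(sum(w^2)); with all weights equal to
    1 this reduces to :func:`activity_zscore`. If more than 90% of
    called targets share one DE direction the stream is flagged biased
    and downstream consumers require |z| > 2.
    """
    universe = de.universe
    targets = set(regulon["target"]) & universe
    if not targets:
        return None, None, False
    called_set = de.called_genes
    k = len(called_set & targets)
    table = [
        [k, len(targets) - k],
        [len(called_set) - k, len(universe) - len(targets) - (len(called_set) - k)],
    ]
    p = fisher_exact_2x2(table, alternative="greater")

    called = _called_targets(de, regulon)
    if called.empty:
        return p, None, False
    lfc = de.table["log2fc"].reindex(called["target"]).abs().to_numpy()
    ranks = pd.Series(lfc).rank(method="average").to_numpy()
    w = ranks / len(ranks)
    consistency = (called["direction"] * called["sign"]).to_numpy()
    z = float((w * consistency).sum() / math.sqrt((w**2).sum()))
    frac_up = (called["direction"] > 0).mean()
    biased = bool(max(frac_up, 1 - frac_up) > 0.9)
    return p, z, biased


def expression_zscore(
    de: DEComparison, regulon: pd.DataFrame, tf: str
) -> tuple[float | None, str]:
    """Functional class from unsigned target movement and the TF's own DE.

    z_e = (n_up - n_down)/sqrt(n_up + n_down) over called targets. If
    |z_e| > 2 and the TF itself is DE-called, matching directions make
    it an activator, opposite directions a repressor; otherwise
    "unclear".
    """
    called = _called_targets(de, regulon)
    if called.empty:
        return None, "unclear"
    n_up = (called["direction"] > 0).sum()
    n_down = (called["direction"] < 0).sum()
    z_e = float((n_up - n_down) / math.sqrt(n_up + n_down))
    tf_dir = de.direction_of(tf)
    if abs(z_e) <= 2 or tf_dir == 0:
        return z_e, "unclear"
    return z_e, "activator" if tf_dir * np.sign(z_e) > 0 else "repressor"


def motif_accessibility_scores(
    motif_hits: pd.DataFrame,
    open_peaks: set[str],
    closed_peaks: set[str],
) -> pd.DataFrame:
    """Per-TF chromatin accessibility z and motif q-value.

    For each TF, compares motif frequency in opened versus closed
    differential peaks with a two-proportion z-test (pooled variance);
    q-values come from Fisher's exact test BH-adjusted across TFs.
    Empty differential peak sets yield an empty frame (absent
    evidence).
    """
    n_open, n_closed = len(open_peaks), len(closed_peaks)
    if n_open == 0 or n_closed == 0:
        return pd.DataFrame(columns=["tf", "z", "p", "q"])
    rows = []
    for tf in sorted(motif_hits["tf"].unique()):
        hit_peaks = set(motif_hits.loc[motif_hits["tf"] == tf, "peak_id"])
        x1 = len(hit_peaks & open_peaks)
        x2 = len(hit_peaks & closed_peaks)
        p1, p2 = x1 / n_open, x2 / n_closed
        pooled = (x1 + x2) / (n_open + n_closed)
        denom = math.sqrt(pooled * (1 - pooled) * (1 / n_open + 1 / n_closed))
        z = (p1 - p2) / denom if denom > 0 else 0.0
        p = fisher_exact_2x2(
            [[x1, n_open - x1], [x2, n_closed - x2]], alternative="two-sided"
        )
        rows.append({"tf": tf, "z": z, "p": p})
    out = pd.DataFrame(rows, columns=["tf", "z", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def _available_streams(ev: TFEvidence) -> list[float]:
    streams = []
    if ev.activity_z is not None:
        streams.append(ev.activity_z)
    if ev.upstream_z is not None:
        if not (ev.upstream_biased and abs(ev.upstream_z) <= 2):
            streams.append(ev.upstream_z)
    return streams


def assign_activity_status(evidence: TFEvidence) -> str:
    """Map assembled z evidence onto the 5-level activity scale.

    Two streams agreeing in sign with both |z| > 2 give a full call;
    agreement with weaker support (or a single stream with |z| > 1)
    gives a "possibly" call; sign disagreement or uniformly weak
    evidence (all |z| <= 1) is unknown/contradictory. A DE-called TF
    whose own direction opposes the call downgrades it one level
    toward unknown.
    """
    streams = _available_streams(evidence)
    if not streams:
        return "unknown/contradictory"
    signs = {int(np.sign(z)) for z in streams if z != 0}
    if len(signs) > 1 or signs == set():
        return "unknown/contradictory"
    if all(abs(z) <= 1 for z in streams):
        return "unknown/contradictory"
    direction = signs.pop()
    full = len(streams) == 2 and all(abs(z) > 2 for z in streams)
    if full:
        status = "activated" if direction > 0 else "inhibited"
    else:
        status = "possibly activated" if direction > 0 else "possibly inhibited"
    # own-expression discordance downgrades one level toward unknown
    if (
        evidence.tf_padj is not None
        and evidence.tf_log2fc is not None
        and evidence.tf_padj < 0.05
        and np.sign(evidence.tf_log2fc) * direction < 0
    ):
        idx = STATUS_LEVELS.index(status)
        mid = STATUS_LEVELS.index("unknown/contradictory")
        status = STATUS_LEVELS[idx - 1 if idx > mid else idx + 1]
    return status


def _predicted_direction(status: str) -> int:
    if status in ("activated", "possibly activated"):
        return 1
    if status in ("inhibited", "possibly inhibited"):
        return -1
    return 0


def trust_score(evidence: TFEvidence, status: str) -> tuple[int, dict[str, bool]]:
    """0-6 confidence score, one point per satisfied criterion.

    (1) regulon over-representation adjusted p < 0.05; (2) upstream
    overlap p < 0.05; (3) full activated/inhibited status; (4) both z
    streams unidirectional with |z| > 2; (5) the TF's own DE concordant
    with the predicted direction; (6) accessibility validation
    (|z_a| > 2, motif q < 0.05, direction concordant).
    """
    direction = _predicted_direction(status)
    ev = evidence
    criteria = {
        "overlap_enrichment": ev.overlap_padj is not None and ev.overlap_padj < 0.05,
        "upstream_p": ev.upstream_p is not None and ev.upstream_p < 0.05,
        "full_status": status in ("activated", "inhibited"),
        "both_z_strong": (
            ev.activity_z is not None
            and ev.upstream_z is not None
            and np.sign(ev.activity_z) == np.sign(ev.upstream_z)
            and abs(ev.activity_z) > 2
            and abs(ev.upstream_z) > 2
        ),
        "expression_concordant": (
            direction != 0
            and ev.tf_padj is not None
            and ev.tf_log2fc is not None
            and ev.tf_padj < 0.05
            and np.sign(ev.tf_log2fc) * direction > 0
        ),
        "accessibility_validated": (
            direction != 0
            and ev.accessibility_z is not None
            and ev.motif_q is not None
            and abs(ev.accessibility_z) > 2
            and ev.motif_q < 0.05
            and np.sign(ev.accessibility_z) * direction > 0
        ),
    }
    return sum(criteria.values()), {k: bool(v) for k, v in criteria.items()}


def filter_by_trust(
    reports: list[TFActivityReport], min_avg_trust: float = 1.0
) -> list[str]:
    """TFs whose mean trust across comparisons is strictly above the bar."""
    by_tf: dict[str, list[int]] = {}
    for r in reports:
        by_tf.setdefault(r.tf, []).append(r.trust)
    return sorted(
        tf for tf, trusts in by_tf.items() if float(np.mean(trusts)) > min_avg_trust
    )


def filter_term_size(
    gene_sets: dict[str, set[str]], size_min: int = 15, size_max: int = 500
) -> dict[str, set[str]]:
    """Keep sets with size strictly between the bounds (>15 and <500)."""
    return {
        name: members
        for name, members in gene_sets.items()
        if size_min < len(members) < size_max
    }


def _upper_quartile_points(values: pd.DataFrame) -> pd.Series:
    """One point per attribute strictly above its column's 75th percentile.

    Quartiles use linear interpolation; with all-equal columns nothing
    strictly exceeds the quartile, so no points are awarded.
    """
    points = pd.Series(0, index=values.index)
    for col in values.columns:
        q3 = values[col].quantile(0.75, interpolation="linear")
        points += (values[col] > q3).astype(int)
    return points


def map_tf_to_clusters(
    targets_by_comparison: dict[str, dict[str, dict[str, set[str]]]],
    cluster_sets: dict[str, set[str]],
    universe: set[str],
    trust_by_tf: dict[str, float],
    literature_flags: dict[str, bool],
    fdr: float = 0.05,
    min_comparisons: int = 8,
    score_min: int = 2,
) -> pd.DataFrame:
    """Recurrent TF-to-functional-cluster mapping with quartile scoring.

    ``targets_by_comparison`` maps comparison -> TF -> {"up": set,
    "down": set}. Per comparison each (TF, direction, cluster) triple is
    tested hypergeometrically against the cluster set (BH within the
    comparison); a (TF, cluster) pair counts a comparison when either
    direction passes the FDR. Pairs recurring in >= ``min_comparisons``
    comparisons are scored: one point per attribute (number of
    comparisons, % of the TF's enriched hits in this cluster, -log10
    mean minimum FDR, average trust) strictly above the upper quartile
    within the cluster, plus one literature point; pairs with score >=
    ``score_min`` are selected.
    """
    cluster_members = {c: set(m) & universe for c, m in cluster_sets.items()}
    bad = [c for c, m in cluster_members.items() if not m]
    if bad:
        raise ValueError(f"cluster sets outside the universe: {bad[:5]}")
    hit_rows = []
    for comparison, per_tf in targets_by_comparison.items():
        tests = []
        for tf, directions in per_tf.items():
            for direction, targets in directions.items():
                targets = set(targets) & universe
                if not targets:
                    continue
                for cluster, members in cluster_members.items():
                    k = len(targets & members)
                    p = hypergeom_tail(k, len(members), len(targets), len(universe))
                    tests.append((tf, direction, cluster, p))
        if not tests:
            continue
        padj = bh_adjust([t[3] for t in tests])
        frame = pd.DataFrame(
            tests, columns=["tf", "direction", "cluster", "p"]
        ).assign(padj=padj, comparison=comparison)
        best = (
            frame.groupby(["tf", "cluster"], as_index=False)
            .agg(min_fdr=("padj", "min"))
            .assign(comparison=comparison)
        )
        hit_rows.append(best[best["min_fdr"] < fdr])
    if not hit_rows:
        return pd.DataFrame(
            columns=["tf", "cluster", "n_comparisons", "score", "selected"]
        )
    hits = pd.concat(hit_rows, ignore_index=True)

    per_pair = hits.groupby(["tf", "cluster"]).agg(
        n_comparisons=("comparison", "nunique"),
        mean_min_fdr=("min_fdr", "mean"),
    )
    per_tf_hits = hits.groupby("tf")["comparison"].count()
    eligible = per_pair[per_pair["n_comparisons"] >= min_comparisons].reset_index()
    if eligible.empty:
        return pd.DataFrame(
            columns=["tf", "cluster", "n_comparisons", "score", "selected"]
        )
    eligible["pct_cluster_hits"] = [
        100.0
        * len(hits[(hits["tf"] == tf) & (hits["cluster"] == cl)])
        / per_tf_hits[tf]
        for tf, cl in zip(eligible["tf"], eligible["cluster"])
    ]
    eligible["neglog_min_fdr"] = -np.log10(
        np.maximum(eligible["mean_min_fdr"], 1e-300)
    )
    eligible["avg_trust"] = [trust_by_tf.get(tf, 0.0) for tf in eligible["tf"]]
    eligible["literature"] = [
        bool(literature_flags.get(tf, False)) for tf in eligible["tf"]
    ]
    attrs = ["n_comparisons", "pct_cluster_hits", "neglog_min_fdr", "avg_trust"]
    scores = []
    for _, grp in eligible.groupby("cluster"):
        pts = _upper_quartile_points(grp[attrs]) + grp["literature"].astype(int)
        scores.append(pts)
    eligible["score"] = pd.concat(scores).reindex(eligible.index)
    eligible["selected"] = eligible["score"] >= score_min
    return eligible.sort_values(["tf", "cluster"]).reset_index(drop=True)


def sasp_tf_profiling(
    up_targets_by_comparison: dict[str, dict[str, set[str]]],
    sasp_by_comparison: dict[str, set[str]],
    category_map: dict[str, str],
    secreted_genes: set[str],
    trust_by_tf: dict[str, float],
    motif_in_sasp_promoter: dict[str, set[str]],
    p_threshold: float = 0.05,
    min_comparisons: int = 8,
    score_min: int = 2,
    min_padj_comparisons: int = 3,
) -> pd.DataFrame:
    """TF regulation of SASP GO:MF categories with quartile selection.

    For each comparison, the TF's upregulated targets are intersected
    with that comparison's SASP genes; each of the 12 GO:MF categories
    is tested hypergeometrically (universe = the comparison's SASP
    set), with BH across (TF, category) tests. (TF, category) pairs
    with raw p < ``p_threshold`` in >= ``min_comparisons`` comparisons
    are scored by upper-quartile points over: % secreted among targets,
    number of comparisons with p < 0.05, number with adjusted p < 0.05,
    -log10 average p, and average trust; plus one point if the TF's
    motif occurs in the promoter of at least one SASP gene of the
    category. Selection needs score >= ``score_min`` and >=
    ``min_padj_comparisons`` comparisons with adjusted p < 0.05.
    """
    rows = []
    for comparison, per_tf in up_targets_by_comparison.items():
        sasp = set(sasp_by_comparison.get(comparison, set()))
        if not sasp:
            continue
        cat_members = {}
        for g in sasp:
            cat = category_map.get(g)
            if cat:
                cat_members.setdefault(cat, set()).add(g)
        tests = []
        for tf, up_targets in per_tf.items():
            sasp_targets = set(up_targets) & sasp
            n_secreted = len(set(up_targets) & secreted_genes)
            pct_secreted = (
                100.0 * n_secreted / len(up_targets) if up_targets else 0.0
            )
            for cat, members in sorted(cat_members.items()):
                k = len(sasp_targets & members)
                p = hypergeom_tail(k, len(members), len(sasp_targets), len(sasp))
                tests.append((tf, cat, p, pct_secreted))
        if not tests:
            continue
        padj = bh_adjust([t[2] for t in tests])
        for (tf, cat, p, pct), q in zip(tests, padj):
            rows.append(
                {
                    "tf": tf,
                    "category": cat,
                    "comparison": comparison,
                    "p": p,
                    "padj": q,
                    "pct_secreted": pct,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["tf", "category", "n_p05", "n_padj05", "score", "selected"]
        )
    tests_df = pd.DataFrame(rows)
    agg = tests_df.groupby(["tf", "category"]).agg(
        n_p05=("p", lambda s: int((s < p_threshold).sum())),
        n_padj05=("padj", lambda s: int((s < 0.05).sum())),
        mean_p=("p", "mean"),
        pct_secreted=("pct_secreted", "mean"),
    )
    eligible = agg[agg["n_p05"] >= min_comparisons].reset_index()
    if eligible.empty:
        return pd.DataFrame(
            columns=["tf", "category", "n_p05", "n_padj05", "score", "selected"]
        )
    eligible["neglog_mean_p"] = -np.log10(np.maximum(eligible["mean_p"], 1e-300))
    eligible["avg_trust"] = [trust_by_tf.get(tf, 0.0) for tf in eligible["tf"]]
    eligible["motif_point"] = [
        bool(
            motif_in_sasp_promoter.get(tf, set())
            & {
                g
                for g, c in category_map.items()
                if c == cat
            }
        )
        for tf, cat in zip(eligible["tf"], eligible["category"])
    ]
    attrs = ["pct_secreted", "n_p05", "n_padj05", "neglog_mean_p", "avg_trust"]
    scores = []
    for _, grp in eligible.groupby("category"):
        pts = _upper_quartile_points(grp[attrs]) + grp["motif_point"].astype(int)
        scores.append(pts)
    eligible["score"] = pd.concat(scores).reindex(eligible.index)
    eligible["selected"] = (eligible["score"] >= score_min) & (
        eligible["n_padj05"] >= min_padj_comparisons
    )
    return eligible.sort_values(["tf", "category"]).reset_index(drop=True)
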