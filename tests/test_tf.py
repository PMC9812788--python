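"""TF activity consensus: z-scores, 5-level status, trust, quartile scoring."""

import numpy as np
import pandas as pd
import pytest

from senprof.tf import (
    STATUS_LEVELS,
    TFActivityReport,
    TFEvidence,
    activity_zscore,
    assign_activity_status,
    expression_zscore,
    filter_by_trust,
    filter_term_size,
    map_tf_to_clusters,
    motif_accessibility_scores,
    regulon_overlap_enrichment,
    sasp_tf_profiling,
    trust_score,
    upstream_regulator_z,
)
from senprof.stats import hypergeom_tail
from tests.conftest import make_de


def regulon(targets_signs, tf="TF1"):
    return pd.DataFrame(
        [
            {"tf": tf, "target": t, "sign": s, "source": "x"}
            for t, s in targets_signs
        ]
    )


def de_with(up=(), down=(), ns=(), comparison="c"):
    rows = {}
    for g in up:
        rows[g] = (2.0, 0.001, 0.01)
    for g in down:
        rows[g] = (-2.0, 0.001, 0.01)
    for g in ns:
        rows[g] = (0.1, 0.5, 0.9)
    return make_de(rows, comparison)


class TestActivityZ:
    def test_nine_activating_up(self):
        genes = [f"g{i}" for i in range(9)]
        de = de_with(up=genes)
        z = activity_zscore(de, regulon([(g, 1) for g in genes]))
        assert z == pytest.approx(3.0)

    def test_balanced_is_zero(self):
        de = de_with(up=["a", "b"], down=["c", "d"])
        z = activity_zscore(de, regulon([(g, 1) for g in "abcd"]))
        assert z == pytest.approx(0.0)

    def test_four_inhibiting_up(self):
        de = de_with(up=["a", "b", "c", "d"])
        z = activity_zscore(de, regulon([(g, -1) for g in "abcd"]))
        assert z == pytest.approx(-2.0)

    def test_antisymmetric_under_sign_flip(self):
        de = de_with(up=["a", "b", "c"], down=["d"])
        reg = regulon([("a", 1), ("b", 1), ("c", -1), ("d", 1)])
        flipped = reg.assign(sign=-reg["sign"])
        assert activity_zscore(de, reg) == pytest.approx(
            -activity_zscore(de, flipped)
        )

    def test_no_called_targets_is_absent(self):
        de = de_with(ns=["a", "b"])
        assert activity_zscore(de, regulon([("a", 1), ("b", 1)])) is None


class TestUpstreamZ:
    def test_equal_weights_reduce_to_activity_z(self):
        # identical |log2FC| across targets -> identical rank weights
        genes = [f"g{i}" for i in range(9)]
        de = de_with(up=genes, ns=["x1", "x2", "x3"])
        reg = regulon([(g, 1) for g in genes])
        _, z, _ = upstream_regulator_z(de, reg)
        assert z == pytest.approx(activity_zscore(de, reg))

    def test_bias_flag_when_one_direction_dominates(self):
        genes = [f"g{i}" for i in range(10)]
        de = de_with(up=genes, ns=["x"])
        reg = regulon([(g, s) for g, s in zip(genes, [1] * 7 + [-1] * 3)])
        _, _, biased = upstream_regulator_z(de, reg)
        assert biased

    def test_overlap_p_is_one_sided_fisher(self):
        de = de_with(up=["a", "b"], ns=["c", "d", "e", "f"])
        reg = regulon([("a", 1), ("b", 1), ("c", 1)])
        p, _, _ = upstream_regulator_z(de, reg)
        assert p == pytest.approx(hypergeom_tail(2, 3, 2, 6), rel=1e-9)


class TestExpressionZ:
    def test_tf_up_targets_up_is_activator(self):
        genes = [f"g{i}" for i in range(9)]
        de = de_with(up=genes + ["TF1"])
        z, cls = expression_zscore(de, regulon([(g, 1) for g in genes]), "TF1")
        assert z == pytest.approx(3.0)
        assert cls == "activator"

    def test_tf_up_targets_down_is_repressor(self):
        genes = [f"g{i}" for i in range(9)]
        de = de_with(down=genes, up=["TF1"])
        _, cls = expression_zscore(de, regulon([(g, 1) for g in genes]), "TF1")
        assert cls == "repressor"

    def test_tf_not_de_is_unclear(self):
        genes = [f"g{i}" for i in range(9)]
        de = de_with(up=genes, ns=["TF1"])
        _, cls = expression_zscore(de, regulon([(g, 1) for g in genes]), "TF1")
        assert cls == "unclear"


class TestAccessibilityZ:
    def test_equal_frequencies_zero(self):
        hits = pd.DataFrame(
            {"peak_id": [f"o{i}" for i in range(50)] + [f"c{i}" for i in range(50)],
             "tf": "TF1"}
        )
        open_p = {f"o{i}" for i in range(100)}
        closed_p = {f"c{i}" for i in range(100)}
        out = motif_accessibility_scores(hits, open_p, closed_p)
        assert out.loc[0, "z"] == pytest.approx(0.0)

    def test_two_proportion_formula(self):
        hits = pd.DataFrame(
            {"peak_id": [f"o{i}" for i in range(80)] + [f"c{i}" for i in range(20)],
             "tf": "TF1"}
        )
        open_p = {f"o{i}" for i in range(100)}
        closed_p = {f"c{i}" for i in range(100)}
        out = motif_accessibility_scores(hits, open_p, closed_p)
        assert out.loc[0, "z"] == pytest.approx(8.4853, abs=1e-3)

    def test_no_differential_peaks_absent(self):
        hits = pd.DataFrame({"peak_id": ["p1"], "tf": ["TF1"]})
        out = motif_accessibility_scores(hits, set(), {"p1"})
        assert len(out) == 0


class TestStatusAssignment:
    def test_both_strong_positive_activated(self):
        ev = TFEvidence(tf="t", activity_z=3.0, upstream_z=3.0)
        assert assign_activity_status(ev) == "activated"

    def test_both_strong_negative_inhibited(self):
        ev = TFEvidence(tf="t", activity_z=-3.0, upstream_z=-2.5)
        assert assign_activity_status(ev) == "inhibited"

    def test_single_moderate_stream_possibly(self):
        ev = TFEvidence(tf="t", activity_z=1.5)
        assert assign_activity_status(ev) == "possibly activated"

    def test_contradictory_streams_unknown(self):
        ev = TFEvidence(tf="t", activity_z=3.0, upstream_z=-3.0)
        assert assign_activity_status(ev) == "unknown/contradictory"

    def test_uniformly_weak_unknown(self):
        ev = TFEvidence(tf="t", activity_z=0.5, upstream_z=0.8)
        assert assign_activity_status(ev) == "unknown/contradictory"

    def test_no_stream_unknown(self):
        assert assign_activity_status(TFEvidence(tf="t")) == "unknown/contradictory"

    def test_own_expression_discordance_downgrades(self):
        ev = TFEvidence(
            tf="t", activity_z=3.0, upstream_z=3.0, tf_log2fc=-2.0, tf_padj=0.01
        )
        assert assign_activity_status(ev) == "possibly activated"

    def test_biased_weak_upstream_stream_dropped(self):
        ev = TFEvidence(tf="t", upstream_z=1.5, upstream_biased=True)
        assert assign_activity_status(ev) == "unknown/contradictory"

    def test_status_vocabulary_closed(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ev = TFEvidence(
                tf="t",
                activity_z=float(rng.normal(0, 3)) if rng.random() < 0.8 else None,
                upstream_z=float(rng.normal(0, 3)) if rng.random() < 0.8 else None,
                upstream_biased=bool(rng.random() < 0.3),
                tf_log2fc=float(rng.normal()),
                tf_padj=float(rng.random()),
            )
            assert assign_activity_status(ev) in STATUS_LEVELS


class TestTrustScore:
    def full_evidence(self):
        return TFEvidence(
            tf="t",
            overlap_padj=0.01,
            upstream_p=0.01,
            upstream_z=3.0,
            activity_z=3.0,
            tf_log2fc=2.0,
            tf_padj=0.01,
            accessibility_z=3.0,
            motif_q=0.01,
        )

    def test_all_six(self):
        score, crit = trust_score(self.full_evidence(), "activated")
        assert score == 6 and all(crit.values())

    def test_none(self):
        score, crit = trust_score(TFEvidence(tf="t"), "unknown/contradictory")
        assert score == 0 and not any(crit.values())

    def test_specific_subset(self):
        # criteria 1 (overlap), 3 (full status), 5 (concordant own DE) only
        ev = TFEvidence(
            tf="t",
            overlap_padj=0.01,
            upstream_p=0.5,
            activity_z=2.5,
            upstream_z=None,
            tf_log2fc=1.0,
            tf_padj=0.01,
        )
        score, crit = trust_score(ev, "activated")
        assert score == 3
        assert crit["overlap_enrichment"] and crit["full_status"]
        assert crit["expression_concordant"]
        assert not crit["both_z_strong"] and not crit["upstream_p"]

    def test_monotone_in_criteria(self):
        ev = self.full_evidence()
        s_all, _ = trust_score(ev, "activated")
        ev.motif_q = 0.5  # drop the accessibility criterion
        s_less, _ = trust_score(ev, "activated")
        assert s_all == s_less + 1


class TestTrustFilter:
    def mk(self, tf, trusts):
        return [
            TFActivityReport(
                tf=tf,
                comparison=f"c{i}",
                status="activated",
                trust=t,
                criteria={},
                evidence=TFEvidence(tf=tf),
            )
            for i, t in enumerate(trusts)
        ]

    def test_exact_mean_one_dropped(self):
        assert filter_by_trust(self.mk("t", [1, 1, 1])) == []

    def test_above_one_retained(self):
        assert filter_by_trust(self.mk("t", [2, 1])) == ["t"]

    def test_single_comparison(self):
        assert filter_by_trust(self.mk("t", [2])) == ["t"]


class TestOverlapEnrichment:
    def test_matches_oracle_small_universe(self):
        de = de_with(up=["a", "b"], down=["c"], ns=["d", "e", "f", "g", "h"])
        reg = regulon([("a", 1), ("b", 1), ("c", -1), ("d", 1)])
        out = regulon_overlap_enrichment(de, reg)
        assert out.loc[0, "p"] == pytest.approx(hypergeom_tail(3, 4, 3, 8))

    def test_disjoint_regulon_skipped(self):
        de = de_with(up=["a"], ns=["b"])
        reg = regulon([("zzz", 1)])
        with pytest.warns(RuntimeWarning):
            out = regulon_overlap_enrichment(de, reg)
        assert len(out) == 0


class TestTermSizeFilter:
    def test_strict_bounds(self):
        sets = {
            "small": set(map(str, range(15))),
            "ok": set(map(str, range(16))),
            "big": set(map(str, range(500))),
            "fine": set(map(str, range(499))),
        }
        kept = filter_term_size(sets)
        assert set(kept) == {"ok", "fine"}


def cluster_fixture(n_enriched_comparisons):
    """12 comparisons; TF_A's up targets match cluster C1 in the first k."""
    universe = {f"g{i}" for i in range(40)}
    cluster_sets = {"C1": {f"g{i}" for i in range(8)}, "C2": {f"g{i}" for i in range(20, 28)}}
    targets = {}
    for i in range(12):
        per_tf = {}
        if i < n_enriched_comparisons:
            per_tf["TF_A"] = {"up": {f"g{j}" for j in range(6)}, "down": set()}
        else:
            per_tf["TF_A"] = {"up": {f"g{j}" for j in range(30, 36)}, "down": set()}
        per_tf["TF_B"] = {"up": {f"g{j}" for j in range(6)}, "down": set()}
        targets[f"cmp{i}"] = per_tf
    return targets, cluster_sets, universe


class TestMapTFToClusters:
    def test_eligibility_boundary(self):
        trust = {"TF_A": 3.0, "TF_B": 2.0}
        lit = {"TF_A": True}
        t8, cs, uni = cluster_fixture(8)
        out8 = map_tf_to_clusters(t8, cs, uni, trust, lit)
        assert ("TF_A", "C1") in set(zip(out8["tf"], out8["cluster"]))
        t7, cs, uni = cluster_fixture(7)
        out7 = map_tf_to_clusters(t7, cs, uni, trust, lit)
        assert ("TF_A", "C1") not in set(zip(out7["tf"], out7["cluster"]))

    def test_equal_attributes_give_no_quartile_points(self):
        # two TFs with identical profiles: nothing strictly exceeds the
        # upper quartile, so only literature points can score
        trust = {"TF_A": 2.0, "TF_B": 2.0}
        t, cs, uni = cluster_fixture(12)
        t = {c: {tf: v for tf, v in per.items()} for c, per in t.items()}
        for per in t.values():
            per["TF_B"] = dict(per["TF_A"])
        out = map_tf_to_clusters(t, cs, uni, trust, {"TF_A": True})
        row_a = out[(out["tf"] == "TF_A") & (out["cluster"] == "C1")].iloc[0]
        row_b = out[(out["tf"] == "TF_B") & (out["cluster"] == "C1")].iloc[0]
        assert row_a["score"] == 1 and row_b["score"] == 0

    def test_cluster_outside_universe_raises(self):
        t, cs, uni = cluster_fixture(8)
        cs["bad"] = {"nope"}
        with pytest.raises(ValueError):
            map_tf_to_clusters(t, cs, uni, {}, {})


class TestSASPTFProfiling:
    def fixture(self):
        """Three cytokine-enriched TFs so quartile scoring can separate them."""
        sasp = {f"s{i}" for i in range(20)}
        cat_map = {f"s{i}": ("cytokine" if i < 10 else "chemokine") for i in range(20)}
        up_targets = {}
        sasp_by_cmp = {}
        for c in range(12):
            cmp_id = f"cmp{c}"
            sasp_by_cmp[cmp_id] = sasp
            up_targets[cmp_id] = {
                "TF_A": {f"s{i}" for i in range(8)},  # strongest cytokine driver
                "TF_C": {f"s{i}" for i in range(2, 8)},
                "TF_D": {f"s{i}" for i in range(4, 10)},
            }
        return up_targets, sasp_by_cmp, cat_map

    def test_planted_driver_selected(self):
        up, sasp_by, cat = self.fixture()
        out = sasp_tf_profiling(
            up,
            sasp_by,
            cat,
            secreted_genes=set(cat),
            trust_by_tf={"TF_A": 3.0, "TF_C": 1.0, "TF_D": 0.5},
            motif_in_sasp_promoter={"TF_A": {"s0"}},
        )
        row = out[(out["tf"] == "TF_A") & (out["category"] == "cytokine")]
        # strongest enrichment + highest trust + motif point -> score >= 2
        assert len(row) == 1 and bool(row.iloc[0]["selected"])

    def test_tf_without_sasp_targets_dropped(self):
        up, sasp_by, cat = self.fixture()
        for c in up:
            up[c]["TF_C"] = {"x1", "x2"}  # not SASP genes
        out = sasp_tf_profiling(
            up, sasp_by, cat, set(cat), {"TF_A": 3.0}, {}
        )
        assert "TF_C" not in set(out["tf"])

    def test_audit_columns_present(self):
        up, sasp_by, cat = self.fixture()
        out = sasp_tf_profiling(up, sasp_by, cat, set(cat), {}, {})
        for col in ("pct_secreted", "n_p05", "n_padj05", "avg_trust", "score"):
            assert col in out.columns
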