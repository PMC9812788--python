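"""Planted-truth recovery and null-calibration studies.

Each routine generates fresh synthetic worlds, runs the relevant
pipeline stage, and scores the result against the planted ground
truth. They are the package's standard way of measuring what the
method recovers under known conditions; the acceptance script and the
test suite both call them.
"""

from __future__ import annotations

import numpy as np

from . import ligrec as ligrec_mod
from . import tf as tf_mod
from .expression import population_id, population_mean
from .sasp import select_sasp_genes
from .synth import (
    WorldConfig,
    generate_world,
    simulate_atac,
    simulate_expression,
)
from .atac import group_average_promoters, ma_summary

__all__ = [
    "null_interaction_rate",
    "channel_recovery",
    "tf_recovery",
    "sasp_recovery",
    "atac_shift_recovery",
]


def _focal_populations(cfg: WorldConfig) -> tuple[list[str], str]:
    tp, age = cfg.timepoints[0], cfg.ages[-1]
    senders = [population_id(ct, "Sen", tp, age) for ct in cfg.cell_types]
    receiver = population_id(cfg.cell_types[0], "NSen", tp, age)
    return senders, receiver


def _run_ligrec(world, tpm, n_perm=100, sd_multiplier=2.0, seed=0):
    senders, receiver = _focal_populations(world.config)
    receiver_mean = population_mean(tpm, receiver)
    regulation = ligrec_mod.receptor_tf_regulation(
        world.signalling_graph, receiver_mean
    )
    candidates = []
    for sender in senders:
        sender_mean = population_mean(tpm, sender)
        candidates.extend(
            ligrec_mod.reconstruct_interactions(
                sender_mean, receiver_mean, world.lr_scaffold, regulation,
                sender, receiver,
            )
        )
    return ligrec_mod.score_and_test(
        candidates, tpm, n_perm=n_perm, sd_multiplier=sd_multiplier, seed=seed
    )


def null_interaction_rate(n_seeds: int = 20, seed: int = 0) -> tuple[int, int]:
    """(significant, total) interactions in worlds with no planted effects.

    Populations are exchangeable (planted effect 0, no channels), so
    flagged interactions are false positives of the mean + 2 s.d. rule.
    """
    n_sig = n_tot = 0
    for i in range(n_seeds):
        world = generate_world(WorldConfig(n_active_channels=0), seed=seed + i)
        tpm, _ = simulate_expression(world, effect_log2fc=0.0, seed=seed + 1000 + i)
        scored = _run_ligrec(world, tpm, seed=seed + 2000 + i)
        n_sig += sum(r.significant for r in scored)
        n_tot += len(scored)
    return n_sig, n_tot


def channel_recovery(
    n_seeds: int = 10,
    seed: int = 0,
    channel_log2fc: float = 3.0,
    dispersion: float = 0.1,
    n_reps: int = 4,
) -> tuple[int, int]:
    """(recovered, planted) channels flagged significant with regulated TFs.

    A planted channel counts as recovered when its exact
    (sender, ligand, receptor, receiver) record is significant and
    carries a non-empty receptor-to-TF regulation set.
    """
    recovered = planted = 0
    for i in range(n_seeds):
        world = generate_world(
            WorldConfig(channel_log2fc=channel_log2fc), seed=seed + i
        )
        tpm, _ = simulate_expression(
            world, dispersion=dispersion, n_reps=n_reps, seed=seed + 1000 + i
        )
        scored = _run_ligrec(world, tpm, seed=seed + 2000 + i)
        flagged = {
            (r.sender, r.ligand, r.receptor, r.receiver)
            for r in scored
            if r.significant and r.regulated_tfs
        }
        truth = set(world.truth.active_channels)
        planted += len(truth)
        recovered += len(truth & flagged)
    return recovered, planted


def tf_recovery(
    n_seeds: int = 20, seed: int = 0, min_trust: int = 3
) -> dict[str, int]:
    """Planted-vs-null TF calls on the focal Sen-vs-NSen comparison.

    A TF counts as called when its status is the full "activated" or
    "inhibited" level with trust >= ``min_trust``; a planted TF counts
    as correctly recovered only if the direction matches the planted
    status.
    """
    counts = {"planted_called": 0, "planted_total": 0, "null_called": 0, "null_total": 0}
    for i in range(n_seeds):
        world = generate_world(WorldConfig(), seed=seed + i)
        _, des = simulate_expression(world, seed=seed + 1000 + i)
        focal = des[0]
        statuses = world.truth.active_tfs[focal.comparison]
        regulons = world.regulons
        overlap = tf_mod.regulon_overlap_enrichment(focal, regulons).set_index("tf")
        for tf_name in world.tfs:
            reg = regulons[regulons["tf"] == tf_name]
            z1 = tf_mod.activity_zscore(focal, reg)
            up_p, up_z, biased = tf_mod.upstream_regulator_z(focal, reg)
            tf_lfc = tf_padj = None
            if tf_name in focal.table.index:
                tf_lfc = float(focal.table.at[tf_name, "log2fc"])
                tf_padj = float(focal.table.at[tf_name, "padj"])
            ev = tf_mod.TFEvidence(
                tf=tf_name,
                overlap_padj=(
                    float(overlap.at[tf_name, "padj"])
                    if tf_name in overlap.index
                    else None
                ),
                upstream_p=up_p,
                upstream_z=up_z,
                upstream_biased=biased,
                activity_z=z1,
                tf_log2fc=tf_lfc,
                tf_padj=tf_padj,
            )
            status = tf_mod.assign_activity_status(ev)
            trust, _ = tf_mod.trust_score(ev, status)
            called = status in ("activated", "inhibited") and trust >= min_trust
            if tf_name in statuses:
                counts["planted_total"] += 1
                counts["planted_called"] += int(called and status == statuses[tf_name])
            else:
                counts["null_total"] += 1
                counts["null_called"] += int(called)
    return counts


def sasp_recovery(n_seeds: int = 10, seed: int = 0) -> tuple[int, int]:
    """(recovered, planted) SASP genes on the focal comparison per seed."""
    recovered = planted = 0
    for i in range(n_seeds):
        world = generate_world(WorldConfig(), seed=seed + i)
        _, des = simulate_expression(world, seed=seed + 1000 + i)
        focal = des[0]
        evidence = world.gene_table[
            ["go_cc_extracellular", "secreted_db", "experimental_sasp"]
        ].astype(bool)
        sset = select_sasp_genes(focal, evidence)
        truth = set(world.truth.sasp_genes[focal.comparison])
        planted += len(truth)
        recovered += len(truth & sset.genes)
    return recovered, planted


def atac_shift_recovery(n_seeds: int = 20, seed: int = 0) -> tuple[int, int]:
    """(recovered, planted) promoter shifts landing in the right MA bin.

    A planted |log2FC| = 2 promoter counts as recovered when it passes
    the signal > 5 filter and its M value exceeds the +-1 bound in the
    planted direction.
    """
    recovered = planted = 0
    for i in range(n_seeds):
        world = generate_world(WorldConfig(), seed=seed + i)
        peaks, _, _ = simulate_atac(world, seed=seed + 1000 + i)
        scores = group_average_promoters(peaks)
        table, _, _ = ma_summary(scores, "NSen", "Sen")
        for pid, lfc in world.truth.shifted_promoters.items():
            planted += 1
            if pid in table.index:
                m = table.at[pid, "M"]
                recovered += int(m > 1.0 if lfc > 0 else m < -1.0)
    return recovered, planted
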