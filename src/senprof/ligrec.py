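"""Ligand-receptor communication networks from bulk population profiles.

Bulk adaptation of FunRes-style reconstruction: transcription factors
and receptors with population-mean expression above 1 TPM count as
expressed; a Markov-chain random walk on the expressed part of the
signalling graph (transition probabilities proportional to the target
node's mean TPM, expressed TFs absorbing) links receptors to the TFs
they regulate; a ligand-receptor interaction between a sender and a
receiver population is called when (1) the receptor is expressed in
the receiver and regulates at least one TF, (2) the ligand is
expressed in the sender and (3) the pair is in the scaffold. The
interaction score is the product of the population-mean ligand and
receptor expression; significance comes from permuting population
labels (default 100 times) and requiring the observed score to be at
least ``sd_multiplier`` (default 2) standard deviations above the
permutation mean. Only significant interactions enter the final
network; all candidates are kept in the audit output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import networkx as nx

from .expression import PopulationExpression, is_expressed, population_mean

__all__ = [
    "InteractionRecord",
    "expressed_tfs",
    "receptor_tf_regulation",
    "reconstruct_interactions",
    "score_and_test",
    "interactions_to_frame",
]


@dataclass
class InteractionRecord:
    """One candidate sender-ligand-receptor-receiver channel."""

    sender: str
    receiver: str
    ligand: str
    receptor: str
    regulated_tfs: frozenset[str]
    score: float = float("nan")
    perm_mean: float = float("nan")
    perm_sd: float = float("nan")
    significant: bool = False


def expressed_tfs(
    receiver_mean_tpm: pd.Series, tfs: list[str], threshold: float = 1.0
) -> set[str]:
    """TFs whose receiver-population mean TPM strictly exceeds the gate."""
    present = [t for t in tfs if t in receiver_mean_tpm.index]
    gate = is_expressed(receiver_mean_tpm[present], threshold)
    return set(gate.index[gate])


def receptor_tf_regulation(
    graph: nx.DiGraph,
    receiver_mean_tpm: pd.Series,
    threshold: float = 1.0,
    reach_threshold: float = 0.1,
    max_steps: int = 10,
) -> dict[str, set[str]]:
    """Receptor -> regulated-TF sets by absorbing random walk.

    The graph is restricted to expressed nodes (mean TPM strictly above
    ``threshold``; missing expression counts as 0). Expressed TFs are
    absorbing. From node u the walk moves to out-neighbour v with
    probability proportional to v's mean TPM. Absorption probabilities
    are accumulated over at most ``max_steps`` steps; a receptor
    regulates a TF iff its absorption probability reaches
    ``reach_threshold``. A receptor with no expressed out-path simply
    regulates nothing.
    """
    tpm = receiver_mean_tpm
    node_class = nx.get_node_attributes(graph, "node_class")
    expressed = {
        n
        for n in graph.nodes
        if n in tpm.index and tpm[n] > threshold
    }
    sub = graph.subgraph(expressed)
    tfs = {n for n in sub.nodes if node_class.get(n) == "tf"}
    receptors = [n for n in sub.nodes if node_class.get(n) == "receptor"]

    # transition rows: TF nodes absorb; others spread mass by target TPM
    out: dict[str, set[str]] = {}
    succ = {
        n: [(v, float(tpm[v])) for v in sub.successors(n) if n not in tfs]
        for n in sub.nodes
    }
    for rec in receptors:
        mass = {rec: 1.0}
        absorbed: dict[str, float] = {}
        for _ in range(max_steps):
            nxt: dict[str, float] = {}
            for node, m in mass.items():
                targets = succ[node]
                total = sum(w for _, w in targets)
                if total <= 0:
                    continue  # dangling mass dissipates
                for v, w in targets:
                    share = m * w / total
                    if v in tfs:
                        absorbed[v] = absorbed.get(v, 0.0) + share
                    else:
                        nxt[v] = nxt.get(v, 0.0) + share
            mass = nxt
            if not mass:
                break
        out[rec] = {t for t, p in absorbed.items() if p >= reach_threshold}
    return out


def reconstruct_interactions(
    sender_mean_tpm: pd.Series,
    receiver_mean_tpm: pd.Series,
    scaffold: pd.DataFrame,
    regulation_map: dict[str, set[str]],
    sender: str,
    receiver: str,
    threshold: float = 1.0,
) -> list[InteractionRecord]:
    """Candidate interactions meeting the three reconstruction conditions."""
    if scaffold.empty:
        raise ValueError("ligand-receptor scaffold is empty")
    records = []
    for _, row in scaffold.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        regulated = regulation_map.get(rec, set())
        if not regulated:
            continue
        if lig not in sender_mean_tpm.index or sender_mean_tpm[lig] <= threshold:
            continue
        if rec not in receiver_mean_tpm.index or receiver_mean_tpm[rec] <= threshold:
            continue
        records.append(
            InteractionRecord(
                sender=sender,
                receiver=receiver,
                ligand=lig,
                receptor=rec,
                regulated_tfs=frozenset(regulated),
            )
        )
    return records


def score_and_test(
    interactions: list[InteractionRecord],
    expr: PopulationExpression,
    n_perm: int = 100,
    sd_multiplier: float = 2.0,
    seed: int = 0,
) -> list[InteractionRecord]:
    """Score interactions and flag significance against a permutation null.

    Observed score = mean ligand TPM over the sender population times
    mean receptor TPM over the receiver. Each permutation shuffles the
    population labels across the whole sample collection, draws
    pseudo-sender and pseudo-receiver groups of the original sizes from
    the relabelled pool, and recomputes the scores; an interaction is
    significant iff its observed score is at least ``sd_multiplier``
    standard deviations (ddof=1) above the permutation mean. A
    degenerate zero-spread null with observed equal to the mean is not
    significant.
    """
    if not interactions:
        return []
    rng = np.random.default_rng(seed)
    values = expr.values
    out: list[InteractionRecord] = []
    by_pair: dict[tuple[str, str], list[InteractionRecord]] = {}
    for rec in interactions:
        by_pair.setdefault((rec.sender, rec.receiver), []).append(rec)

    for (sender, receiver), recs in by_pair.items():
        s_samples = expr.samples_of(sender)
        r_samples = expr.samples_of(receiver)
        if len(s_samples) < 2 or len(r_samples) < 2:
            raise ValueError(
                f"need >=2 samples per population for {sender} / {receiver}"
            )
        lig_idx = [r.ligand for r in recs]
        rec_idx = [r.receptor for r in recs]
        obs = (
            values.loc[lig_idx, s_samples].mean(axis=1).to_numpy()
            * values.loc[rec_idx, r_samples].mean(axis=1).to_numpy()
        )
        pool = list(values.columns)
        n_s, n_r = len(s_samples), len(r_samples)
        lig_mat = values.loc[lig_idx, pool].to_numpy()
        rec_mat = values.loc[rec_idx, pool].to_numpy()
        perm_scores = np.empty((n_perm, len(recs)))
        for p in range(n_perm):
            order = rng.permutation(len(pool))
            perm_scores[p] = (
                lig_mat[:, order[:n_s]].mean(axis=1)
                * rec_mat[:, order[n_s : n_s + n_r]].mean(axis=1)
            )
        mean = perm_scores.mean(axis=0)
        sd = perm_scores.std(axis=0, ddof=1)
        for i, rec in enumerate(recs):
            if sd[i] == 0.0:
                sig = obs[i] > mean[i]
                if obs[i] == mean[i]:
                    warnings.warn(
                        "zero-variance permutation null with observed equal "
                        "to the mean; interaction not significant",
                        RuntimeWarning,
                        stacklevel=2,
                    )
            else:
                sig = obs[i] >= mean[i] + sd_multiplier * sd[i]
            out.append(
                InteractionRecord(
                    sender=rec.sender,
                    receiver=rec.receiver,
                    ligand=rec.ligand,
                    receptor=rec.receptor,
                    regulated_tfs=rec.regulated_tfs,
                    score=float(obs[i]),
                    perm_mean=float(mean[i]),
                    perm_sd=float(sd[i]),
                    significant=bool(sig),
                )
            )
    return out


def interactions_to_frame(interactions: list[InteractionRecord]) -> pd.DataFrame:
    """Audit table of all candidate interactions (sorted, deterministic)."""
    rows = [
        {
            "sender": r.sender,
            "receiver": r.receiver,
            "ligand": r.ligand,
            "receptor": r.receptor,
            "regulated_tfs": ",".join(sorted(r.regulated_tfs)),
            "score": r.score,
            "perm_mean": r.perm_mean,
            "perm_sd": r.perm_sd,
            "significant": r.significant,
        }
        for r in interactions
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "sender",
            "receiver",
            "ligand",
            "receptor",
            "regulated_tfs",
            "score",
            "perm_mean",
            "perm_sd",
            "significant",
        ],
    )
    return frame.sort_values(
        ["sender", "receiver", "ligand", "receptor"]
    ).reset_index(drop=True)
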