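"""Signalling-pathway impact analysis of ligand-receptor interactions.

For each significant interaction, the DE log2FC of its regulated
target TFs in the receiving population perturbs signed pathway
topologies. Two evidence components per (interaction, pathway):

* pNDE — hypergeometric over-representation of the DE targets among
  the pathway's genes (shared code path with the enrichment module);
* pPERT — the tail probability of the net total accumulation
  tA = sum(PF - dE), where perturbation factors solve
  PF(g) = dE(g) + sum_u beta[u->g] * PF(u) / N_ds(u),
  under bootstrap re-assignment of the observed dE values to random
  pathway genes (default 2,000 draws).

The components combine by Fisher's product method; pathways passing
BH-adjusted combined p (pGFdr) < 0.05 are significant, with status
activated when tA > 0 and inhibited otherwise. Interaction ratios
report, per pathway, the fraction of analysed interactions that
activate or inhibit it, with a deterministic top-k per direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, fishers_product, hypergeom_tail

__all__ = [
    "PathwayTopology",
    "PathwayImpact",
    "spia_impact",
    "fdr_and_select",
    "interaction_ratio",
]


@dataclass
class PathwayTopology:
    """Signed influence topology: genes and beta[u -> g] in {-1, 0, +1}."""

    pathway_id: str
    genes: list[str]
    beta: np.ndarray  # beta[i, j] = influence of gene j on gene i

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ValueError(f"pathway {self.pathway_id}: duplicate genes")
        if self.beta.shape != (n, n):
            raise ValueError(
                f"pathway {self.pathway_id}: beta shape {self.beta.shape} != ({n},{n})"
            )
        if not np.isin(self.beta, (-1.0, 0.0, 1.0)).all():
            raise ValueError(f"pathway {self.pathway_id}: beta entries must be -1/0/+1")

    @classmethod
    def from_edges(
        cls, pathway_id: str, genes: list[str], edges: list[tuple[str, str, int]]
    ) -> "PathwayTopology":
        idx = {g: i for i, g in enumerate(genes)}
        beta = np.zeros((len(genes), len(genes)))
        for src, dst, sign in edges:
            beta[idx[dst], idx[src]] = sign
        return cls(pathway_id, list(genes), beta)

    @property
    def downstream_counts(self) -> np.ndarray:
        """N_ds(u): number of genes each gene directly influences (min 1)."""
        return np.maximum(np.abs(self.beta).sum(axis=0), 1.0)


@dataclass
class PathwayImpact:
    pathway_id: str
    interaction_id: str
    tA: float
    pNDE: float
    pPERT: float
    pG: float
    status: str
    pGFdr: float = float("nan")


def _perturbation_matrix(topology: PathwayTopology) -> np.ndarray:
    """(I - B)^-1 with B = beta normalized by downstream counts."""
    B = topology.beta / topology.downstream_counts[np.newaxis, :]
    n = len(topology.genes)
    A = np.eye(n) - B
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError(
            f"pathway {topology.pathway_id}: singular (I - B) system "
            "(cyclic unit-weight loop)"
        )
    return np.linalg.inv(A)


def spia_impact(
    de_targets: dict[str, float],
    topology: PathwayTopology,
    reference: set[str],
    interaction_id: str = "",
    n_boot: int = 2000,
    seed: int = 0,
) -> PathwayImpact:
    """Impact of one interaction's DE targets on one pathway.

    ``de_targets`` maps the interaction's DE target genes to their
    log2FC (dE); pathway genes not in it carry dE = 0. ``reference`` is
    the gene universe (all target TFs across analysed interactions).
    pNDE is the hypergeometric tail of the DE-target overlap with the
    pathway inside that universe; pPERT is the two-sided bootstrap tail
    of |tA| under random re-assignment of the observed dE values to
    pathway genes.
    """
    if not de_targets:
        raise ValueError("no DE targets supplied")
    genes = topology.genes
    pathway_in_ref = set(genes) & reference
    de_in_ref = set(de_targets) & reference
    pNDE = hypergeom_tail(
        len(de_in_ref & set(genes)),
        len(pathway_in_ref),
        len(de_in_ref),
        len(reference),
    )

    M = _perturbation_matrix(topology)
    dE = np.array([de_targets.get(g, 0.0) for g in genes])
    PF = M @ dE
    tA = float((PF - dE).sum())

    rng = np.random.default_rng(seed)
    observed_values = np.array([v for v in de_targets.values()])
    n_assign = min(len(observed_values), len(genes))
    colsum = (M - np.eye(len(genes))).sum(axis=0)  # tA = colsum . dE
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pos = rng.choice(len(genes), size=n_assign, replace=False)
        vals = rng.choice(observed_values, size=n_assign, replace=False)
        boots[b] = float(colsum[pos] @ vals)
    pPERT = (np.count_nonzero(np.abs(boots) >= abs(tA) - 1e-12) + 1) / (n_boot + 1)

    pG = fishers_product(pNDE, float(pPERT))
    return PathwayImpact(
        pathway_id=topology.pathway_id,
        interaction_id=interaction_id,
        tA=tA,
        pNDE=pNDE,
        pPERT=float(pPERT),
        pG=pG,
        status="activated" if tA > 0 else "inhibited",
    )


def fdr_and_select(
    impacts: list[PathwayImpact], fdr: float = 0.05
) -> list[PathwayImpact]:
    """BH-adjust combined p across pathways; keep pGFdr < fdr."""
    if not impacts:
        return []
    padj = bh_adjust([i.pG for i in impacts])
    out = []
    for imp, q in zip(impacts, padj):
        imp.pGFdr = float(q)
        if q < fdr:
            out.append(imp)
    return out


def interaction_ratio(
    impacts: list[PathwayImpact],
    n_interactions: int,
    top_k: int = 8,
) -> pd.DataFrame:
    """Per-pathway activating/inhibiting interaction ratios with top-k.

    ratio = (#interactions with that signed status on the pathway) /
    (total interactions analysed). Ranking is descending by ratio with
    ties broken by pathway id; the top ``top_k`` per direction are
    flagged.
    """
    if n_interactions < 1:
        raise ValueError("need at least one analysed interaction")
    rows: dict[str, dict[str, int]] = {}
    for imp in impacts:
        entry = rows.setdefault(imp.pathway_id, {"activated": 0, "inhibited": 0})
        entry[imp.status] += 1
    frame = pd.DataFrame(
        [
            {
                "pathway": pw,
                "activating_ratio": c["activated"] / n_interactions,
                "inhibiting_ratio": c["inhibited"] / n_interactions,
            }
            for pw, c in sorted(rows.items())
        ],
        columns=["pathway", "activating_ratio", "inhibiting_ratio"],
    )
    for direction in ("activating", "inhibiting"):
        col = f"{direction}_ratio"
        ranked = frame.sort_values(
            [col, "pathway"], ascending=[False, True]
        )
        top = set(ranked.head(top_k).loc[ranked[col] > 0, "pathway"])
        frame[f"top_{direction}"] = frame["pathway"].isin(top)
    return frame
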