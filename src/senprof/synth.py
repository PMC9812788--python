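"""Self-contained synthetic world with planted ground truth.

Emulates the inputs of the downstream pipeline without any download:
a gene table with secreted-protein evidence and GO:MF categories,
signed TF regulons with planted activity, a layered receptor-to-TF
signalling graph, a ligand-receptor scaffold with planted active
channels, toy signed pathway topologies, negative-binomial bulk counts
for the full population design (3 cell types x {Sen, NSen, basal} x
2 timepoints x 2 ages), and ATAC peak counts with planted promoter
accessibility shifts.

Counts are negative binomial in the mean-dispersion parameterization
(variance = mu + phi * mu^2), matching the model behind the consumed
DE tables. The generator's internal DE stand-in is Welch's t-test on
log2(TPM + 1) with BH adjustment; it is a stand-in for the consumed DE
tables, not a DE method of this package.

Everything is a pure function of (config, seed): identical inputs give
byte-identical serialized output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats as sps

from .atac import PeakTable
from .expression import DEComparison, PopulationExpression, population_id
from .stats import bh_adjust

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "GroundTruth",
    "ConfigError",
    "GOMF_CATEGORIES",
    "generate_world",
    "simulate_expression",
    "simulate_atac",
    "write_world",
]

#: the fixed 12-name GO:MF category vocabulary used for SASP profiling
GOMF_CATEGORIES = (
    "adhesion molecule",
    "chemokine",
    "complement component",
    "cytokine",
    "enzyme",
    "enzyme regulator",
    "extracellular matrix constituent",
    "growth factor",
    "hormone",
    "ligand",
    "proteinase",
    "receptor",
)

EVIDENCE_SOURCES = ("go_cc_extracellular", "secreted_db", "experimental_sasp")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class WorldConfig:
    """Simulation parameters; defaults define the study conditions.

    The design covers 36 population conditions (3 cell types x
    {Sen, NSen, basal} x 2 timepoints x 2 ages) with ``n_reps``
    replicates each. Planted effects: an up-regulated secreted program
    in Sen populations (``n_sasp_planted`` genes at ``effect_log2fc``),
    concordantly shifted regulons for planted activated/inhibited TFs,
    sender-side ligand up-shifts for planted channels
    (``channel_log2fc``), and promoter accessibility shifts
    (``atac_shift_log2fc``).
    """

    n_genes: int = 1200
    n_tfs: int = 40
    n_receptors: int = 24
    n_ligands: int = 24
    n_intermediates: int = 30
    n_secreted: int = 240
    n_sasp_planted: int = 40
    n_lr_pairs: int = 40
    n_active_channels: int = 8
    n_active_tfs: int = 6
    n_repressed_tfs: int = 6
    min_targets: int = 10
    max_targets: int = 20
    cell_types: tuple[str, ...] = ("SC", "FAP", "MC")
    states: tuple[str, ...] = ("Sen", "NSen", "basal")
    timepoints: tuple[str, ...] = ("3dpi", "7dpi")
    ages: tuple[str, ...] = ("young", "old")
    n_reps: int = 4
    effect_log2fc: float = 2.0
    channel_log2fc: float = 3.0
    dispersion: float = 0.05
    count_depth: float = 30.0
    n_pathways: int = 12
    pathway_size: int = 6
    n_channel_program_tfs: int = 6
    n_promoter_peaks: int = 300
    n_background_peaks: int = 100
    n_shifted_promoters: int = 30
    atac_shift_log2fc: float = 2.0
    atac_n_reps: int = 4

    def validate(self) -> None:
        positive = (
            "n_genes",
            "n_tfs",
            "n_receptors",
            "n_ligands",
            "n_intermediates",
            "n_lr_pairs",
            "n_reps",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_genes < 500:
            raise ConfigError(f"n_genes must be >= 500, got {self.n_genes}")
        if self.n_tfs < 5:
            raise ConfigError(f"n_tfs must be >= 5, got {self.n_tfs}")
        if self.n_lr_pairs < 20:
            raise ConfigError(f"n_lr_pairs must be >= 20, got {self.n_lr_pairs}")
        if len(self.cell_types) * len(self.states) < 2:
            raise ConfigError("design must name at least 2 populations")
        role_total = (
            self.n_tfs
            + self.n_receptors
            + self.n_ligands
            + self.n_intermediates
            + self.n_secreted
        )
        if role_total > self.n_genes:
            raise ConfigError(
                f"gene roles require {role_total} genes but n_genes={self.n_genes}"
            )
        if self.n_sasp_planted > self.n_secreted:
            raise ConfigError("n_sasp_planted exceeds n_secreted")
        if self.n_active_tfs + self.n_repressed_tfs > self.n_tfs:
            raise ConfigError("planted TFs exceed n_tfs")
        if self.n_active_channels > self.n_lr_pairs:
            raise ConfigError("n_active_channels exceeds n_lr_pairs")

    @property
    def population_ids(self) -> list[str]:
        return [
            population_id(ct, st, tp, age)
            for ct in self.cell_types
            for st in self.states
            for tp in self.timepoints
            for age in self.ages
        ]

    @property
    def comparisons(self) -> list[tuple[str, str, str]]:
        """Sen-vs-NSen contrasts: (cell_type, timepoint, age) triples."""
        return [
            (ct, tp, age)
            for ct in self.cell_types
            for tp in self.timepoints
            for age in self.ages
        ]


@dataclass
class GroundTruth:
    """Planted entities, disjoint from nuisance ones by construction."""

    active_channels: list[tuple[str, str, str, str]]
    active_tfs: dict[str, dict[str, str]]
    sasp_genes: dict[str, list[str]]
    shifted_promoters: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "active_channels": [list(c) for c in self.active_channels],
            "active_tfs": self.active_tfs,
            "sasp_genes": self.sasp_genes,
            "shifted_promoters": self.shifted_promoters,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            active_channels=[tuple(c) for c in d["active_channels"]],
            active_tfs=d["active_tfs"],
            sasp_genes=d["sasp_genes"],
            shifted_promoters=d["shifted_promoters"],
        )


@dataclass
class SyntheticWorld:
    """Gene table, regulons, graphs and design for one simulated study."""

    config: WorldConfig
    seed: int
    gene_table: pd.DataFrame
    regulons: pd.DataFrame
    signalling_graph: nx.DiGraph
    lr_scaffold: pd.DataFrame
    pathways: dict[str, dict]
    truth: GroundTruth

    @property
    def genes(self) -> list[str]:
        return list(self.gene_table.index)

    @property
    def tfs(self) -> list[str]:
        return list(self.gene_table.index[self.gene_table["role"] == "tf"])

    def genes_of_role(self, role: str) -> list[str]:
        return list(self.gene_table.index[self.gene_table["role"] == role])

    def regulon_of(self, tf: str) -> pd.DataFrame:
        return self.regulons[self.regulons["tf"] == tf]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def generate_world(
    config: WorldConfig | None = None, seed: int = 0
) -> SyntheticWorld:
    """Build a synthetic world with planted ground truth.

    Pure in (config, seed). Every planted channel's receptor reaches at
    least one TF in the signalling graph (rewired if a random draw left
    it dangling); every TF's regulon has at least ``min_targets``
    targets; gene lengths are positive; GO:MF categories come from the
    fixed 12-name list.
    """
    cfg = config or WorldConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    genes = _gene_ids(cfg.n_genes)
    roles = np.array(["filler"] * cfg.n_genes, dtype=object)
    cursor = 0
    role_slices = {}
    for role, size in (
        ("tf", cfg.n_tfs),
        ("receptor", cfg.n_receptors),
        ("ligand", cfg.n_ligands),
        ("intermediate", cfg.n_intermediates),
        ("secreted", cfg.n_secreted),
    ):
        roles[cursor : cursor + size] = role
        role_slices[role] = genes[cursor : cursor + size]
        cursor += size

    lengths = rng.integers(500, 5001, size=cfg.n_genes)
    gene_table = pd.DataFrame(
        {
            "length": lengths,
            "role": roles,
            "chrom": "chr1",
            "tss": 2000 + 5000 * np.arange(cfg.n_genes),
            "strand": "+",
            "go_mf": "",
        },
        index=pd.Index(genes, name="gene"),
    )
    for src in EVIDENCE_SOURCES:
        gene_table[src] = False

    secreted = role_slices["secreted"]
    cats = rng.choice(len(GOMF_CATEGORIES), size=len(secreted))
    gene_table.loc[secreted, "go_mf"] = [GOMF_CATEGORIES[c] for c in cats]
    # every secreted gene carries >=1 evidence source; which sources is random
    ev = rng.random((len(secreted), len(EVIDENCE_SOURCES))) < 0.5
    ev[~ev.any(axis=1), 0] = True
    for j, src in enumerate(EVIDENCE_SOURCES):
        gene_table.loc[secreted, src] = ev[:, j]

    sasp_planted = sorted(rng.choice(secreted, size=cfg.n_sasp_planted, replace=False))

    # --- regulons -------------------------------------------------------
    tfs = role_slices["tf"]
    active_tfs = tfs[: cfg.n_active_tfs]
    repressed_tfs = tfs[cfg.n_active_tfs : cfg.n_active_tfs + cfg.n_repressed_tfs]
    target_pool = np.array(
        [g for g in genes if gene_table.at[g, "role"] in ("secreted", "filler")]
    )
    # planted TFs avoid the planted SASP program (except the designated
    # driver, which regulates it with activating edges) so the planted
    # programs stay disjoint and do not cancel one another
    sasp_set = set(sasp_planted)
    planted_tfs = set(active_tfs) | set(repressed_tfs)
    non_sasp_pool = np.array([g for g in target_pool if g not in sasp_set])
    rows = []
    for tf in tfs:
        n_targets = int(rng.integers(cfg.min_targets, cfg.max_targets + 1))
        pool = non_sasp_pool if tf in planted_tfs else target_pool
        targets = list(rng.choice(pool, size=n_targets, replace=False))
        signs = list(np.where(rng.random(len(targets)) < 0.8, 1, -1))
        if active_tfs and tf == active_tfs[0]:
            # the planted SASP driver: half its regulon is the SASP program
            n_sasp = min(len(sasp_planted), n_targets // 2)
            chosen = list(rng.choice(sasp_planted, size=n_sasp, replace=False))
            targets = chosen + targets[: n_targets - n_sasp]
            signs = [1] * n_sasp + signs[: n_targets - n_sasp]
        for t, s in zip(targets, signs):
            rows.append({"tf": tf, "target": t, "sign": int(s), "source": "synthetic"})
    regulons = pd.DataFrame(rows).drop_duplicates(["tf", "target"]).reset_index(drop=True)

    # --- signalling graph: receptors -> 3 intermediate sublayers -> TFs -
    receptors = role_slices["receptor"]
    inter = role_slices["intermediate"]
    third = max(1, len(inter) // 3)
    layers = [receptors, inter[:third], inter[third : 2 * third], inter[2 * third :], tfs]
    graph = nx.DiGraph()
    for layer_id, layer in enumerate(layers):
        graph.add_nodes_from(
            layer,
            node_class=(
                "receptor" if layer_id == 0 else "tf" if layer_id == 4 else "intermediate"
            ),
        )
    for li in range(len(layers) - 1):
        nxt = layers[li + 1]
        for node in layers[li]:
            k = int(rng.integers(2, min(4, len(nxt)) + 1))
            for tgt in rng.choice(nxt, size=k, replace=False):
                graph.add_edge(node, tgt)
    # forward skip edges keep reachability nontrivial without cycles
    for _ in range(len(receptors)):
        li = int(rng.integers(0, len(layers) - 2))
        lj = int(rng.integers(li + 1, len(layers)))
        u = layers[li][int(rng.integers(len(layers[li])))]
        v = layers[lj][int(rng.integers(len(layers[lj])))]
        if u != v:
            graph.add_edge(u, v)

    # --- ligand-receptor scaffold and planted channels ------------------
    ligands = role_slices["ligand"]
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for i, j in zip(
        rng.integers(0, len(ligands), size=20 * cfg.n_lr_pairs),
        rng.integers(0, len(receptors), size=20 * cfg.n_lr_pairs),
    ):
        pair = (ligands[int(i)], receptors[int(j)])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
        if len(pairs) == cfg.n_lr_pairs:
            break
    if len(pairs) < cfg.n_lr_pairs:
        raise ConfigError("could not draw enough unique ligand-receptor pairs")
    lr_scaffold = pd.DataFrame(pairs, columns=["ligand", "receptor"])

    tf_set = set(tfs)
    receiver = population_id(cfg.cell_types[0], "NSen", cfg.timepoints[0], cfg.ages[-1])
    senders = [
        population_id(ct, "Sen", cfg.timepoints[0], cfg.ages[-1])
        for ct in cfg.cell_types
    ]
    channels: list[tuple[str, str, str, str]] = []
    used_ligands: set[str] = set()
    program_up = list(active_tfs[: cfg.n_channel_program_tfs])
    program_down = list(repressed_tfs[: cfg.n_channel_program_tfs])
    for lig, rec in pairs:
        if len(channels) >= cfg.n_active_channels:
            break
        if lig in used_ligands:
            continue
        # a planted channel's receptor signals straight into a planted TF
        # program (dedicated inflammatory/activating or inhibitory channel)
        program = program_up if len(channels) % 2 == 0 else program_down
        if program:
            graph.remove_edges_from(list(graph.out_edges(rec)))
            for tf in program:
                graph.add_edge(rec, tf)
        channels.append((senders[len(channels) % len(senders)], lig, rec, receiver))
        used_ligands.add(lig)
    channel_receptors = {c[2] for c in channels}
    for rec in receptors:
        # non-channel receptors also signal into a couple of TFs through
        # shallow routes, so reconstructed interactions span the TF layer
        if rec in channel_receptors:
            continue
        for tgt in rng.choice(tfs, size=3, replace=False):
            graph.add_edge(rec, tgt)
    for _, rec in pairs:
        # any receptor left unable to reach a TF gets rewired through the
        # first intermediate sublayer so reachability is a pure gate
        if not _reaches_tf(graph, rec, tf_set):
            via = layers[1][int(rng.integers(len(layers[1])))]
            graph.add_edge(rec, via)

    # --- toy pathway topologies over TF genes ---------------------------
    pathways = _build_pathways(cfg, rng, tfs, active_tfs, repressed_tfs)

    comparisons = [
        f"SenVsNSen.{ct}.{tp}.{age}" for ct, tp, age in cfg.comparisons
    ]
    truth = GroundTruth(
        active_channels=channels,
        active_tfs={
            cmp: {**{tf: "activated" for tf in active_tfs},
                  **{tf: "inhibited" for tf in repressed_tfs}}
            for cmp in comparisons
        },
        sasp_genes={cmp: list(sasp_planted) for cmp in comparisons},
        shifted_promoters={},  # filled by simulate_atac planning below
    )

    world = SyntheticWorld(
        config=cfg,
        seed=seed,
        gene_table=gene_table,
        regulons=regulons,
        signalling_graph=graph,
        lr_scaffold=lr_scaffold,
        pathways=pathways,
        truth=truth,
    )
    _plan_atac_shifts(world, rng)
    return world


def _reaches_tf(graph: nx.DiGraph, receptor: str, tf_set: set[str]) -> bool:
    if receptor not in graph:
        return False
    seen = nx.descendants(graph, receptor)
    return bool(seen & tf_set)


def _build_pathways(cfg, rng, tfs, active_tfs, repressed_tfs) -> dict[str, dict]:
    """Toy signed topologies whose genes are the world's TFs.

    One pathway concentrates the planted activated TFs (the synthetic
    inflammation/SASP program), one the planted inhibited TFs; the rest
    draw genes at random. Edges form a forward chain with sparse signed
    shortcuts, so (I - B) is always invertible.
    """
    pathways: dict[str, dict] = {}
    size = min(cfg.pathway_size, len(tfs))
    for pi in range(cfg.n_pathways):
        name = f"PW{pi + 1:02d}"
        if pi == 0:
            head = list(active_tfs[:size])
            rest = [t for t in tfs if t not in head]
            members = head + list(
                rng.choice(rest, size=max(0, size - len(head)), replace=False)
            )
        elif pi == 1:
            head = list(repressed_tfs[:size])
            rest = [t for t in tfs if t not in head]
            members = head + list(
                rng.choice(rest, size=max(0, size - len(head)), replace=False)
            )
        else:
            members = list(rng.choice(tfs, size=size, replace=False))
        edges = []
        for a, b in zip(members[:-1], members[1:]):
            edges.append((a, b, 1))
        for _ in range(2):
            i = int(rng.integers(0, len(members) - 1))
            j = int(rng.integers(i + 1, len(members)))
            sign = 1 if rng.random() < 0.8 else -1
            edges.append((members[i], members[j], sign))
        pathways[name] = {"genes": list(members), "edges": edges}
    return pathways


def _plan_atac_shifts(world: SyntheticWorld, rng: np.random.Generator) -> None:
    """Choose which promoter peaks carry planted accessibility shifts.

    Opened promoters belong to targets of planted activated TFs, closed
    promoters to targets of planted inhibited TFs, so motif enrichment in
    open-vs-closed regions reflects the planted activities.
    """
    cfg = world.config
    promoter_genes = world.genes[: cfg.n_promoter_peaks]
    comparison0 = next(iter(world.truth.active_tfs))
    statuses = world.truth.active_tfs[comparison0]
    up_pool = sorted(
        set(
            world.regulons.loc[
                world.regulons["tf"].isin(
                    [t for t, s in statuses.items() if s == "activated"]
                )
                & (world.regulons["sign"] == 1),
                "target",
            ]
        )
        & set(promoter_genes)
    )
    down_pool = sorted(
        set(
            world.regulons.loc[
                world.regulons["tf"].isin(
                    [t for t, s in statuses.items() if s == "inhibited"]
                )
                & (world.regulons["sign"] == 1),
                "target",
            ]
        )
        & set(promoter_genes)
    )
    half = cfg.n_shifted_promoters // 2
    n_up = min(half, len(up_pool))
    up = list(rng.choice(up_pool, size=n_up, replace=False)) if n_up else []
    down_pool = [g for g in down_pool if g not in up]
    n_down = min(cfg.n_shifted_promoters - half, len(down_pool))
    down = (
        list(rng.choice(down_pool, size=n_down, replace=False)) if n_down else []
    )
    shifts = {f"peak_{g}": cfg.atac_shift_log2fc for g in up}
    shifts.update({f"peak_{g}": -cfg.atac_shift_log2fc for g in down})
    world.truth.shifted_promoters = shifts


# --- expression simulation ---------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with variance mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _population_multipliers(world: SyntheticWorld, effect_log2fc: float) -> pd.DataFrame:
    """Per-(gene, population) fold multipliers encoding all planted effects."""
    cfg = world.config
    pops = cfg.population_ids
    mult = pd.DataFrame(1.0, index=world.genes, columns=pops)
    sen_pops = [p for p in pops if p.split(".")[1] == "Sen"]
    effect = 2.0**effect_log2fc

    comparison0 = next(iter(world.truth.active_tfs))
    sasp = world.truth.sasp_genes[comparison0]
    mult.loc[sasp, sen_pops] *= effect

    for tf, status in world.truth.active_tfs[comparison0].items():
        reg = world.regulon_of(tf)
        direction = 1.0 if status == "activated" else -1.0
        for _, row in reg.iterrows():
            mult.loc[row["target"], sen_pops] *= 2.0 ** (
                effect_log2fc * direction * row["sign"]
            )
        # the TF's own expression moves with its activity (concordance)
        mult.loc[tf, sen_pops] *= 2.0 ** (effect_log2fc * direction)

    for sender, ligand, _rec, _receiver in world.truth.active_channels:
        mult.loc[ligand, sender] *= 2.0**cfg.channel_log2fc
    return mult


def simulate_expression(
    world: SyntheticWorld,
    effect_log2fc: float | None = None,
    dispersion: float | None = None,
    n_reps: int | None = None,
    seed: int = 0,
) -> tuple[PopulationExpression, list[DEComparison]]:
    """Simulate bulk NB counts and the DE stand-in tables.

    Planted genes have their population means shifted by
    2**effect_log2fc in their planted populations. Twelve Sen-vs-NSen
    DE tables (one per cell type x timepoint x age) carry Welch-test
    p-values on log2(TPM + 1), BH-adjusted, plus the empirical log2FC
    of population means.
    """
    cfg = world.config
    effect_log2fc = cfg.effect_log2fc if effect_log2fc is None else effect_log2fc
    dispersion = cfg.dispersion if dispersion is None else dispersion
    n_reps = cfg.n_reps if n_reps is None else n_reps
    if n_reps < 2:
        raise ConfigError(f"n_reps must be >= 2 (variance undefined), got {n_reps}")
    if dispersion <= 0:
        raise ConfigError(f"dispersion must be positive, got {dispersion}")

    rng = np.random.default_rng(seed)
    genes = world.genes
    G = len(genes)
    lengths = world.gene_table["length"]

    # baseline abundance by role: signalling nodes well expressed so the
    # chain is not severed by the 1 TPM gate; secreted genes robustly
    # expressed (cytokine-like); filler is a mixture with a silent tail
    base = np.empty(G)
    role = world.gene_table["role"].to_numpy()
    node_mask = np.isin(role, ("tf", "receptor", "ligand", "intermediate"))
    secreted_mask = role == "secreted"
    filler_mask = ~node_mask & ~secreted_mask
    base[node_mask] = rng.lognormal(mean=3.0, sigma=0.3, size=node_mask.sum())
    base[secreted_mask] = rng.lognormal(mean=2.5, sigma=0.8, size=secreted_mask.sum())
    n_fill = int(filler_mask.sum())
    fill = rng.lognormal(mean=2.2, sigma=1.0, size=n_fill)
    silent = rng.random(n_fill) < 0.3
    fill[silent] = rng.lognormal(mean=-1.0, sigma=1.0, size=int(silent.sum()))
    base[filler_mask] = fill

    mult = _population_multipliers(world, effect_log2fc)
    pops = cfg.population_ids
    counts = {}
    annotations = []
    len_kb = lengths.to_numpy() / 1000.0
    for pop in pops:
        ct, st, tp, age = pop.split(".")
        mu = base * mult[pop].to_numpy() * len_kb * cfg.count_depth
        for rep in range(1, n_reps + 1):
            sample = f"{pop}.r{rep}"
            counts[sample] = _nb_draw(rng, mu, dispersion)
            annotations.append(
                {
                    "sample": sample,
                    "cell_type": ct,
                    "state": st,
                    "timepoint": tp,
                    "age": age,
                    "replicate": rep,
                }
            )
    count_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"))
    ann_df = pd.DataFrame(annotations).set_index("sample")
    expr = PopulationExpression(count_df, ann_df, lengths, unit="counts")
    tpm = expr.to_tpm()

    de_tables = []
    for ct, tp, age in cfg.comparisons:
        sen = tpm.values[tpm.samples_of(population_id(ct, "Sen", tp, age))]
        nsen = tpm.values[tpm.samples_of(population_id(ct, "NSen", tp, age))]
        de_tables.append(
            DEComparison(f"SenVsNSen.{ct}.{tp}.{age}", _welch_de(sen, nsen))
        )
    return tpm, de_tables


def _welch_de(group_a: pd.DataFrame, group_b: pd.DataFrame) -> pd.DataFrame:
    """Welch's t on log2(TPM+1); the generator's DE-table stand-in."""
    la = np.log2(group_a.to_numpy() + 1.0)
    lb = np.log2(group_b.to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    lfc = np.log2((group_a.mean(axis=1) + 1.0) / (group_b.mean(axis=1) + 1.0))
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": p, "padj": bh_adjust(p)},
        index=group_a.index,
    )


# --- ATAC simulation ----------------------------------------------------


def simulate_atac(
    world: SyntheticWorld,
    seed: int = 0,
    n_reps: int | None = None,
    dispersion: float | None = None,
) -> tuple[PeakTable, pd.DataFrame, pd.DataFrame]:
    """Simulate ATAC peak counts, the peak DE stand-in and motif hits.

    Returns (peak table, peak DE table, motif-hit table). Promoter
    peaks sit within TSS +- 1 kb of their gene by construction; planted
    shifted promoters have Sen-group count means scaled by the planted
    fold change. Motif hits of planted activated TFs concentrate in
    opened promoters (and of inhibited TFs in closed ones), emulating
    motif enrichment in differentially accessible regions.
    """
    cfg = world.config
    n_reps = cfg.atac_n_reps if n_reps is None else n_reps
    dispersion = cfg.dispersion if dispersion is None else dispersion
    if n_reps < 2:
        raise ConfigError(f"n_reps must be >= 2, got {n_reps}")
    rng = np.random.default_rng(seed)

    promoter_genes = world.genes[: cfg.n_promoter_peaks]
    gt = world.gene_table
    rows = []
    for g in promoter_genes:
        tss = int(gt.at[g, "tss"])
        rows.append(
            {
                "peak_id": f"peak_{g}",
                "chrom": gt.at[g, "chrom"],
                "start": tss - 400,
                "end": tss + 200,
                "annotation": "promoter-TSS",
                "gene": g,
                "tss": tss,
            }
        )
    max_tss = int(gt["tss"].max())
    for i in range(cfg.n_background_peaks):
        start = max_tss + 10_000 + 2_000 * i
        rows.append(
            {
                "peak_id": f"bgpeak_{i:04d}",
                "chrom": "chr1",
                "start": start,
                "end": start + int(rng.integers(200, 900)),
                "annotation": "intergenic",
                "gene": "",
                "tss": np.nan,
            }
        )
    meta = pd.DataFrame(rows).set_index("peak_id")

    base = rng.lognormal(mean=3.5, sigma=0.8, size=len(meta))
    shift = np.ones(len(meta))
    for pid, lfc in world.truth.shifted_promoters.items():
        shift[meta.index.get_loc(pid)] = 2.0**lfc
    len_kb = (meta["end"] - meta["start"]).to_numpy() / 1000.0

    counts = {}
    groups = {}
    for grp, mult in (("Sen", shift), ("NSen", np.ones(len(meta)))):
        mu = base * mult * len_kb * 20.0
        for rep in range(1, n_reps + 1):
            sample = f"ATAC.{grp}.r{rep}"
            counts[sample] = _nb_draw(rng, mu, dispersion)
            groups[sample] = grp
    count_df = pd.DataFrame(counts, index=meta.index)
    peaks = PeakTable(meta=meta, counts=count_df, groups=pd.Series(groups))

    norm = peaks.normalized()
    sen_cols = [s for s, g in groups.items() if g == "Sen"]
    nsen_cols = [s for s, g in groups.items() if g == "NSen"]
    peak_de = _welch_de(norm[sen_cols], norm[nsen_cols])

    comparison0 = next(iter(world.truth.active_tfs))
    statuses = world.truth.active_tfs[comparison0]
    opened = {p for p, l in world.truth.shifted_promoters.items() if l > 0}
    closed = {p for p, l in world.truth.shifted_promoters.items() if l < 0}
    hit_rows = []
    for tf in world.tfs:
        status = statuses.get(tf, "none")
        for pid in meta.index:
            p_hit = 0.1
            if status == "activated" and pid in opened:
                p_hit = 0.75
            elif status == "inhibited" and pid in closed:
                p_hit = 0.75
            if rng.random() < p_hit:
                hit_rows.append({"peak_id": pid, "tf": tf})
    motif_hits = pd.DataFrame(hit_rows, columns=["peak_id", "tf"])
    return peaks, peak_de, motif_hits


# --- serialization ------------------------------------------------------


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Serialize the world to plain-text files (TSV/GMT/JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.gene_table.to_csv(out / "genes.tsv", sep="\t")
    world.regulons.to_csv(out / "regulons.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(world.signalling_graph.edges), columns=["source", "target"]
    ).to_csv(out / "signalling_edges.tsv", sep="\t", index=False)
    world.lr_scaffold.to_csv(out / "lr_scaffold.tsv", sep="\t", index=False)
    with open(out / "pathways.json", "w") as fh:
        json.dump(world.pathways, fh, indent=1, sort_keys=True)
    with open(out / "ground_truth.json", "w") as fh:
        fh.write(world.truth.to_json())
    with open(out / "gomf_sets.gmt", "w") as fh:
        for cat in GOMF_CATEGORIES:
            members = sorted(
                world.gene_table.index[world.gene_table["go_mf"] == cat]
            )
            if members:
                key = cat.replace(" ", "_")
                fh.write("\t".join([key, "GO:MF category"] + members) + "\n")
    with open(out / "config.json", "w") as fh:
        json.dump({"seed": world.seed, **asdict(world.config)}, fh, indent=1, sort_keys=True)
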