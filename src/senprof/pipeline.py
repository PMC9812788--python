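"""Stage orchestration over a serialized data directory.

``run_simulate`` materializes a synthetic world (expression, DE
tables, ATAC, regulons, scaffold, signalling graph, pathways, gene
sets) into one directory; the other stages read that directory, run
one pipeline step, write TSV/JSON outputs plus a deterministic
manifest, and return their main result. The CLI is a thin shell over
these functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from . import atac as atac_mod
from . import io as pio
from . import ligrec as ligrec_mod
from . import sasp as sasp_mod
from . import spia as spia_mod
from . import tf as tf_mod
from .config import RunConfig
from .expression import DEComparison, PopulationExpression, population_id, population_mean
from .synth import (
    GroundTruth,
    SyntheticWorld,
    WorldConfig,
    generate_world,
    simulate_atac,
    simulate_expression,
    write_world,
)

__all__ = [
    "DataDir",
    "run_simulate",
    "run_sasp",
    "run_tf_consensus",
    "run_ligrec",
    "run_spia",
    "run_atac",
    "run_aging_mhg",
    "run_report",
]


@dataclass
class DataDir:
    """Lazy view of a simulate output directory."""

    path: Path

    def __post_init__(self) -> None:
        self.path = Path(self.path)

    def _need(self, name: str) -> Path:
        p = self.path / name
        if not p.exists():
            raise FileNotFoundError(f"missing {name} in {self.path}")
        return p

    @property
    def world_config(self) -> dict:
        with open(self._need("config.json")) as fh:
            return json.load(fh)

    @property
    def gene_table(self) -> pd.DataFrame:
        return pd.read_csv(self._need("genes.tsv"), sep="\t", index_col=0)

    @property
    def expression(self) -> PopulationExpression:
        return pio.read_expression(
            self._need("expression.tsv"), self._need("samples.tsv"), unit="tpm"
        )

    @property
    def de_tables(self) -> list[DEComparison]:
        de_dir = self._need("de")
        return [pio.read_de_table(p) for p in sorted(de_dir.glob("*.tsv"))]

    @property
    def regulons(self) -> pd.DataFrame:
        return pio.read_regulons(self._need("regulons.tsv"))

    @property
    def scaffold(self) -> pd.DataFrame:
        return pio.read_scaffold(self._need("lr_scaffold.tsv"))

    @property
    def signalling_graph(self) -> nx.DiGraph:
        edges = pio.read_edge_list(self._need("signalling_edges.tsv"))
        roles = self.gene_table["role"]
        g = nx.DiGraph()
        for _, row in edges.iterrows():
            g.add_edge(row["source"], row["target"])
        classes = {"tf": "tf", "receptor": "receptor"}
        nx.set_node_attributes(
            g,
            {n: classes.get(roles.get(n, ""), "intermediate") for n in g.nodes},
            "node_class",
        )
        return g

    @property
    def peaks(self) -> atac_mod.PeakTable:
        return pio.read_bed_peaks(
            self._need("atac_peaks.bed"), self._need("atac_counts.tsv")
        )

    @property
    def peak_de(self) -> pd.DataFrame:
        return pd.read_csv(self._need("atac_peak_de.tsv"), sep="\t", index_col=0)

    @property
    def motif_hits(self) -> pd.DataFrame:
        return pd.read_csv(self._need("motif_hits.tsv"), sep="\t")

    @property
    def pathways(self) -> dict:
        with open(self._need("pathways.json")) as fh:
            return json.load(fh)

    @property
    def gomf_sets(self) -> dict[str, set[str]]:
        return pio.read_gmt(self._need("gomf_sets.gmt"))

    @property
    def aging_sets(self) -> dict[str, set[str]]:
        return pio.read_gmt(self._need("aging_sets.gmt"))

    @property
    def ground_truth(self) -> GroundTruth:
        with open(self._need("ground_truth.json")) as fh:
            return GroundTruth.from_json(fh.read())

    @property
    def evidence(self) -> pd.DataFrame:
        gt = self.gene_table
        cols = ["go_cc_extracellular", "secreted_db", "experimental_sasp"]
        return gt[cols].astype(bool)

    @property
    def category_map(self) -> dict[str, str]:
        gt = self.gene_table
        return {
            g: c
            for g, c in gt["go_mf"].items()
            if isinstance(c, str) and c
        }

    def focal_populations(self) -> tuple[list[str], str]:
        """Sender Sen populations and the focal NSen receiver.

        The study's communication analysis sends from the three
        senescent populations of old mice at the early regeneration
        timepoint into the non-senescent stem-cell population.
        """
        cfg = self.world_config
        tp, age = cfg["timepoints"][0], cfg["ages"][-1]
        senders = [
            population_id(ct, "Sen", tp, age) for ct in cfg["cell_types"]
        ]
        receiver = population_id(cfg["cell_types"][0], "NSen", tp, age)
        return senders, receiver

    def focal_comparison(self) -> str:
        cfg = self.world_config
        return (
            f"SenVsNSen.{cfg['cell_types'][0]}.{cfg['timepoints'][0]}"
            f".{cfg['ages'][-1]}"
        )


def run_simulate(
    out_dir: str | Path,
    seed: int = 0,
    world_config: WorldConfig | None = None,
) -> SyntheticWorld:
    """Generate and serialize the full synthetic data directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = generate_world(world_config, seed=seed)
    write_world(world, out)

    tpm, de_tables = simulate_expression(world, seed=seed + 1)
    pio.write_expression(tpm, out / "expression.tsv", out / "samples.tsv")
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    for de in de_tables:
        pio.write_de_table(de, de_dir / f"{de.comparison}.tsv")

    peaks, peak_de, motif_hits = simulate_atac(world, seed=seed + 2)
    pio.write_bed_peaks(peaks, out / "atac_peaks.bed", out / "atac_counts.tsv")
    peak_de.to_csv(out / "atac_peak_de.tsv", sep="\t", float_format="%.6g")
    motif_hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)

    # synthetic ageing signature: part of the planted up-program plus noise,
    # emulating an independently published ageing gene set
    rng = np.random.default_rng(seed + 3)
    comparison0 = next(iter(world.truth.sasp_genes))
    sasp = world.truth.sasp_genes[comparison0]
    overlap = list(rng.choice(sasp, size=min(20, len(sasp)), replace=False))
    others = [g for g in world.genes if g not in set(sasp)]
    noise = list(rng.choice(others, size=30, replace=False))
    pio.write_gmt(
        {"synthetic_aging_signature": set(overlap + noise)},
        out / "aging_sets.gmt",
    )

    pio.write_manifest(
        out / "manifest.simulate.json",
        "simulate",
        inputs={},
        config={"world": "synthetic-default"},
        seed=seed,
    )
    return world


def run_sasp(data_dir: str | Path, cfg: RunConfig | None = None) -> dict:
    """SASP gene sets per comparison plus GO:MF pathway enrichment."""
    cfg = cfg or RunConfig()
    data = DataDir(data_dir)
    evidence = data.evidence
    category_map = data.category_map
    gomf_sets = data.gomf_sets
    out_dir = data.path / "sasp"
    out_dir.mkdir(exist_ok=True)
    results = {}
    for de in data.de_tables:
        sset = sasp_mod.select_sasp_genes(de, evidence, category_map)
        enr = sasp_mod.sasp_pathway_enrichment(
            sset, gomf_sets, de.universe, fdr=cfg.de_padj
        )
        sset.table.to_csv(
            out_dir / f"sasp.{de.comparison}.tsv", sep="\t", float_format="%.6g"
        )
        enr.to_csv(
            out_dir / f"enrichment.{de.comparison}.tsv",
            sep="\t",
            index=False,
            float_format="%.6g",
        )
        results[de.comparison] = sset
    pio.write_manifest(
        data.path / "manifest.sasp.json",
        "sasp",
        inputs={"data": "."},
        config=cfg.to_dict(),
        seed=cfg.seed,
    )
    return results


def _tf_reports_for_comparison(
    de: DEComparison,
    regulons: pd.DataFrame,
    access_scores: pd.DataFrame,
) -> list[tf_mod.TFActivityReport]:
    overlap = tf_mod.regulon_overlap_enrichment(de, regulons).set_index("tf")
    access = (
        access_scores.set_index("tf") if len(access_scores) else pd.DataFrame()
    )
    reports = []
    for tf_name in sorted(regulons["tf"].unique()):
        reg = regulons[regulons["tf"] == tf_name]
        z1 = tf_mod.activity_zscore(de, reg)
        up_p, up_z, biased = tf_mod.upstream_regulator_z(de, reg)
        tf_lfc = tf_padj = None
        if tf_name in de.table.index:
            tf_lfc = float(de.table.at[tf_name, "log2fc"])
            tf_padj = float(de.table.at[tf_name, "padj"])
        z_a = motif_q = None
        if tf_name in getattr(access, "index", []):
            z_a = float(access.at[tf_name, "z"])
            motif_q = float(access.at[tf_name, "q"])
        ev = tf_mod.TFEvidence(
            tf=tf_name,
            overlap_padj=(
                float(overlap.at[tf_name, "padj"]) if tf_name in overlap.index else None
            ),
            upstream_p=up_p,
            upstream_z=up_z,
            upstream_biased=biased,
            activity_z=z1,
            tf_log2fc=tf_lfc,
            tf_padj=tf_padj,
            accessibility_z=z_a,
            motif_q=motif_q,
        )
        status = tf_mod.assign_activity_status(ev)
        trust, criteria = tf_mod.trust_score(ev, status)
        reports.append(
            tf_mod.TFActivityReport(
                tf=tf_name,
                comparison=de.comparison,
                status=status,
                trust=trust,
                criteria=criteria,
                evidence=ev,
            )
        )
    return reports


def run_tf_consensus(data_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Consensus TF activity reports across all comparisons."""
    cfg = cfg or RunConfig()
    data = DataDir(data_dir)
    regulons = data.regulons
    open_peaks, closed_peaks = atac_mod.differential_peaks(
        data.peak_de, padj=cfg.atac_peak_padj, lfc=cfg.atac_lfc
    )
    access = tf_mod.motif_accessibility_scores(
        data.motif_hits, open_peaks, closed_peaks
    )
    all_reports: list[tf_mod.TFActivityReport] = []
    for de in data.de_tables:
        all_reports.extend(_tf_reports_for_comparison(de, regulons, access))
    retained = tf_mod.filter_by_trust(all_reports, min_avg_trust=cfg.trust_min)
    rows = [
        {
            "tf": r.tf,
            "comparison": r.comparison,
            "status": r.status,
            "trust": r.trust,
            "retained": r.tf in retained,
            **{f"crit_{k}": v for k, v in r.criteria.items()},
        }
        for r in all_reports
    ]
    frame = pd.DataFrame(rows).sort_values(["tf", "comparison"]).reset_index(drop=True)
    frame.to_csv(data.path / "tf_reports.tsv", sep="\t", index=False)
    pio.write_manifest(
        data.path / "manifest.tf.json",
        "tf-consensus",
        inputs={"data": "."},
        config=cfg.to_dict(),
        seed=cfg.seed,
    )
    return frame


def run_ligrec(data_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Ligand-receptor interaction reconstruction with permutation test."""
    cfg = cfg or RunConfig()
    data = DataDir(data_dir)
    expr = data.expression
    graph = data.signalling_graph
    scaffold = data.scaffold
    senders, receiver = data.focal_populations()

    receiver_mean = population_mean(expr, receiver)
    regulation = ligrec_mod.receptor_tf_regulation(
        graph,
        receiver_mean,
        threshold=cfg.tpm_expressed,
        reach_threshold=cfg.reach_threshold,
    )
    candidates: list[ligrec_mod.InteractionRecord] = []
    for sender in senders:
        sender_mean = population_mean(expr, sender)
        candidates.extend(
            ligrec_mod.reconstruct_interactions(
                sender_mean,
                receiver_mean,
                scaffold,
                regulation,
                sender,
                receiver,
                threshold=cfg.tpm_expressed,
            )
        )
    scored = ligrec_mod.score_and_test(
        candidates,
        expr,
        n_perm=cfg.n_permutations,
        sd_multiplier=cfg.sd_multiplier,
        seed=cfg.seed,
    )
    frame = ligrec_mod.interactions_to_frame(scored)
    frame.to_csv(
        data.path / "interactions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    frame[frame["significant"]].to_csv(
        data.path / "interactions.significant.tsv",
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    pio.write_manifest(
        data.path / "manifest.ligrec.json",
        "ligrec",
        inputs={"data": "."},
        config=cfg.to_dict(),
        seed=cfg.seed,
    )
    return frame


def run_spia(data_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Downstream pathway impact and interaction ratios."""
    cfg = cfg or RunConfig()
    data = DataDir(data_dir)
    inter_path = data.path / "interactions.significant.tsv"
    if not inter_path.exists():
        raise FileNotFoundError("run ligrec before spia: missing interactions")
    inter = pd.read_csv(inter_path, sep="\t")
    audit = pd.read_csv(data.path / "interactions.tsv", sep="\t")
    de = next(
        d for d in data.de_tables if d.comparison == data.focal_comparison()
    )
    topologies = [
        spia_mod.PathwayTopology.from_edges(
            pid, spec["genes"], [tuple(e) for e in spec["edges"]]
        )
        for pid, spec in sorted(data.pathways.items())
    ]
    # reference universe: target TFs of every reconstructed interaction
    reference: set[str] = set()
    for cell in audit["regulated_tfs"].dropna():
        reference.update(str(cell).split(","))
    reference.discard("")
    per_interaction: list[tuple[str, dict[str, float]]] = []
    for _, row in inter.iterrows():
        tfs = sorted(str(row["regulated_tfs"]).split(",")) if row["regulated_tfs"] else []
        de_targets = {
            t: float(de.table.at[t, "log2fc"])
            for t in tfs
            if de.direction_of(t) != 0
        }
        iid = f"{row['sender']}|{row['ligand']}|{row['receptor']}|{row['receiver']}"
        per_interaction.append((iid, de_targets))

    impacts_rows = []
    analysed = 0
    significant_impacts: list[spia_mod.PathwayImpact] = []
    for idx, (iid, de_targets) in enumerate(per_interaction):
        if not de_targets:
            continue
        analysed += 1
        impacts = [
            spia_mod.spia_impact(
                de_targets,
                topo,
                reference,
                interaction_id=iid,
                n_boot=cfg.spia_nboot,
                seed=cfg.seed + 17 * idx,
            )
            for topo in topologies
        ]
        selected = spia_mod.fdr_and_select(impacts, fdr=cfg.spia_fdr)
        significant_impacts.extend(selected)
        impacts_rows.extend(
            {
                "interaction": i.interaction_id,
                "pathway": i.pathway_id,
                "tA": i.tA,
                "pNDE": i.pNDE,
                "pPERT": i.pPERT,
                "pG": i.pG,
                "pGFdr": i.pGFdr,
                "status": i.status,
                "significant": i in selected,
            }
            for i in impacts
        )
    impacts_frame = pd.DataFrame(impacts_rows)
    impacts_frame.to_csv(
        data.path / "spia_impacts.tsv", sep="\t", index=False, float_format="%.6g"
    )
    ratios = (
        spia_mod.interaction_ratio(significant_impacts, analysed)
        if analysed
        else pd.DataFrame()
    )
    ratios.to_csv(
        data.path / "spia_ratios.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pio.write_manifest(
        data.path / "manifest.spia.json",
        "spia",
        inputs={"data": "."},
        config=cfg.to_dict(),
        seed=cfg.seed,
    )
    return ratios


def run_atac(data_dir: str | Path, cfg: RunConfig | None = None) -> dict:
    """Promoter accessibility scoring and MA summary."""
    cfg = cfg or RunConfig()
    data = DataDir(data_dir)
    peaks = data.peaks
    scores = atac_mod.group_average_promoters(
        peaks, tss_halfwidth=cfg.promoter_halfwidth
    )
    table, n_up, n_down = atac_mod.ma_summary(
        scores,
        "NSen",
        "Sen",
        min_signal=cfg.atac_min_signal,
        lfc_bound=cfg.atac_lfc,
    )
    scores.to_csv(data.path / "atac_promoter_scores.tsv", sep="\t", float_format="%.6g")
    table.to_csv(data.path / "atac_ma.tsv", sep="\t", float_format="%.6g")
    open_peaks, closed_peaks = atac_mod.differential_peaks(
        data.peak_de, padj=cfg.atac_peak_padj, lfc=cfg.atac_lfc
    )
    summary = {
        "n_promoter_peaks": int(len(scores)),
        "n_ma_peaks": int(len(table)),
        "n_lfc_above": n_up,
        "n_lfc_below": n_down,
        "n_open": len(open_peaks),
        "n_closed": len(closed_peaks),
    }
    with open(data.path / "atac_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    pio.write_manifest(
        data.path / "manifest.atac.json",
        "atac",
        inputs={"data": "."},
        config=cfg.to_dict(),
        seed=cfg.seed,
    )
    return summary


def run_aging_mhg(data_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    """mHG comparison of the focal senescence ranking to ageing signatures."""
    cfg = cfg or RunConfig()
    data = DataDir(data_dir)
    de = next(
        d for d in data.de_tables if d.comparison == data.focal_comparison()
    )
    ranked = sasp_mod.rank_genes_by_de(de)
    rows = []
    for name, members in sorted(data.aging_sets.items()):
        res = sasp_mod.aging_overlap_mhg(ranked, members)
        rows.append(
            {
                "aging_set": name,
                "mhg": res.statistic,
                "threshold": res.threshold,
                "b_at_threshold": res.b_at_threshold,
                "pvalue": res.pvalue,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(
        data.path / "aging_mhg.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pio.write_manifest(
        data.path / "manifest.aging_mhg.json",
        "aging-mhg",
        inputs={"data": "."},
        config=cfg.to_dict(),
        seed=cfg.seed,
    )
    return frame


def run_report(data_dir: str | Path) -> dict:
    """Aggregate stage manifests into one provenance record."""
    data = DataDir(data_dir)
    manifests = {}
    for p in sorted(data.path.glob("manifest.*.json")):
        with open(p) as fh:
            manifests[p.stem.replace("manifest.", "")] = json.load(fh)
    report = {"stages": manifests}
    with open(data.path / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
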