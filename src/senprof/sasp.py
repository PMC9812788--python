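"""SASP gene definition, functional profiling and ageing comparison.

A gene belongs to the senescence-associated secretory phenotype (SASP)
of one Sen-vs-NSen comparison when it is significantly upregulated
(adjusted p < 0.05 and log2FC > 0) and there is evidence from at least
one source that it encodes an extracellular or secreted product.
Evidence tables are plain boolean inputs (the sources the study
combined were GO:CC, protein-knowledge bases and experimental SASP
reports); no live database is queried.

SASP sets are profiled by hypergeometric over-representation against
pathway gene sets (BH, FDR < 0.05), classified into the fixed 12 GO:MF
categories, and compared with ageing signatures through the
minimum-hypergeometric test on the DE-ranked gene list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import DEComparison
from .stats import MHGResult, hypergeom_enrichment, mhg_pvalue, mhg_statistic

__all__ = [
    "SASPGeneSet",
    "select_sasp_genes",
    "sasp_pathway_enrichment",
    "classify_gomf",
    "rank_genes_by_de",
    "aging_overlap_mhg",
]


@dataclass
class SASPGeneSet:
    """Per-comparison SASP genes with provenance.

    ``table`` is indexed by gene with columns log2fc, padj, sources
    (comma-joined evidence source names) and category (GO:MF or
    "unclassified").
    """

    comparison: str
    table: pd.DataFrame

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)


def select_sasp_genes(
    de: DEComparison,
    evidence: pd.DataFrame,
    category_map: dict[str, str] | None = None,
) -> SASPGeneSet:
    """Intersect upregulated genes with secreted-protein evidence.

    ``evidence`` is indexed by gene with boolean source columns; genes
    absent from it count as having no evidence. Each retained gene
    keeps the list of sources that supported it.
    """
    if de.table.empty:
        raise ValueError("empty DE table")
    up = de.table.loc[sorted(de.up_genes)]
    ev = evidence.reindex(up.index, fill_value=False).astype(bool)
    if ev.shape[1] == 0:
        raise ValueError("evidence table has no source columns")
    has_any = ev.any(axis=1)
    kept = up[has_any]
    sources = ev.loc[kept.index].apply(
        lambda row: ",".join(ev.columns[row.to_numpy()]), axis=1
    )
    table = pd.DataFrame(
        {
            "log2fc": kept["log2fc"],
            "padj": kept["padj"],
            "sources": sources if len(kept) else pd.Series(dtype=object),
        }
    )
    if category_map is not None:
        table["category"] = classify_gomf(list(table.index), category_map)[0]
    return SASPGeneSet(comparison=de.comparison, table=table)


def sasp_pathway_enrichment(
    sasp: SASPGeneSet,
    pathway_sets: dict[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the SASP set, BH-filtered.

    Returns only the sets passing the configured FDR; the full table is
    available through :func:`senprof.stats.hypergeom_enrichment`.
    """
    if not sasp.genes:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "padj"])
    result = hypergeom_enrichment(sasp.genes, pathway_sets, universe)
    return result[result["padj"] < fdr].reset_index(drop=True)


def classify_gomf(
    genes: list[str], category_map: dict[str, str]
) -> tuple[pd.Series, pd.Series]:
    """Assign each gene its GO:MF category ("unclassified" if unmapped).

    Returns (per-gene category, per-category counts); counts include
    the unclassified bucket, so they sum to the input size.
    """
    cats = pd.Series(
        [category_map.get(g, "unclassified") or "unclassified" for g in genes],
        index=pd.Index(genes, name="gene"),
        dtype=object,
    )
    counts = cats.value_counts().sort_index()
    return cats, counts


def rank_genes_by_de(de: DEComparison) -> list[str]:
    """Genes ranked by descending signed DE significance.

    The metric is sign(log2FC) * (-log10 p); the most significantly
    upregulated genes come first, the most significantly downregulated
    last. Ties break by gene id for determinism.
    """
    t = de.table
    with np.errstate(divide="ignore"):
        metric = np.sign(t["log2fc"]) * -np.log10(np.maximum(t["pvalue"], 1e-300))
    order = pd.DataFrame(
        {"metric": metric.to_numpy(), "gene_id": list(t.index)}
    ).sort_values(["metric", "gene_id"], ascending=[False, True])
    return list(order["gene_id"])


def aging_overlap_mhg(
    ranked_genes: list[str], aging_set: set[str]
) -> MHGResult:
    """mHG enrichment of an ageing signature at the top of a DE ranking."""
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ValueError("ranked gene list contains duplicates")
    members = set(aging_set) & set(ranked_genes)
    if not members:
        raise ValueError("aging set shares no gene with the ranked universe")
    labels = [1 if g in members else 0 for g in ranked_genes]
    if all(labels):
        raise ValueError("aging set covers the whole universe; mHG undefined")
    res = mhg_statistic(labels)
    p = mhg_pvalue(res.statistic, N=len(labels), B=sum(labels))
    return MHGResult(
        statistic=res.statistic,
        threshold=res.threshold,
        b_at_threshold=res.b_at_threshold,
        pvalue=p,
    )
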