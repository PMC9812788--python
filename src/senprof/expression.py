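"""Expression containers, TPM normalization, gating and DE-table handling.

The pipeline operates on bulk profiles of labelled cell populations. A
population is one combination of cell type (SC, FAP, MC), state (Sen,
NSen, basal), timepoint (3dpi, 7dpi, basal) and age (young, old);
replicates of a population are columns of the matrix. Differential
expression tables (one per Sen-vs-NSen contrast) are consumed, not
re-fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationExpression",
    "DEComparison",
    "counts_to_tpm",
    "is_expressed",
    "population_mean",
    "select_lipid_panel",
]

ANNOTATION_FIELDS = ("cell_type", "state", "timepoint", "age")


def population_id(cell_type: str, state: str, timepoint: str, age: str) -> str:
    """Canonical dotted population label, e.g. ``SC.Sen.3dpi.young``."""
    return f"{cell_type}.{state}.{timepoint}.{age}"


@dataclass
class PopulationExpression:
    """Gene x sample matrix with sample-to-population annotations.

    ``values`` is a DataFrame (rows: gene ids, columns: sample ids);
    ``annotations`` a DataFrame indexed by sample id with columns
    cell_type/state/timepoint/age/replicate; ``gene_lengths`` a Series
    of transcript-union lengths in bp. ``unit`` is "counts" or "tpm".
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    gene_lengths: pd.Series
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in expression matrix")
        missing = set(self.values.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(
                f"samples without annotation: {sorted(missing)[:5]}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def populations(self) -> pd.Series:
        """Sample id -> population id for the samples in the matrix."""
        ann = self.annotations.loc[list(self.values.columns)]
        return (
            ann["cell_type"]
            + "."
            + ann["state"]
            + "."
            + ann["timepoint"]
            + "."
            + ann["age"]
        )

    def samples_of(self, population: str) -> list[str]:
        pops = self.populations
        return list(pops.index[pops == population])

    def to_tpm(self) -> "PopulationExpression":
        """Length-normalize counts to TPM; identity if already TPM."""
        if self.unit == "tpm":
            return self
        tpm = counts_to_tpm(self.values, self.gene_lengths)
        return PopulationExpression(
            tpm, self.annotations, self.gene_lengths, unit="tpm"
        )


@dataclass
class DEComparison:
    """Per-gene differential statistics for one contrast.

    ``table`` has index = gene id and columns log2fc, pvalue, padj.
    Direction calls use the configured adjusted-p threshold: up means
    padj < threshold and log2fc > 0, down the mirror image.
    """

    comparison: str
    table: pd.DataFrame
    padj_threshold: float = 0.05

    def __post_init__(self) -> None:
        need = {"log2fc", "pvalue", "padj"}
        if not need <= set(self.table.columns):
            raise ValueError(
                f"DE table missing columns {sorted(need - set(self.table.columns))}"
            )
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene ids in DE table")

    @property
    def up_genes(self) -> set[str]:
        t = self.table
        return set(t.index[(t["padj"] < self.padj_threshold) & (t["log2fc"] > 0)])

    @property
    def down_genes(self) -> set[str]:
        t = self.table
        return set(t.index[(t["padj"] < self.padj_threshold) & (t["log2fc"] < 0)])

    @property
    def called_genes(self) -> set[str]:
        return self.up_genes | self.down_genes

    @property
    def universe(self) -> set[str]:
        return set(self.table.index)

    def direction_of(self, gene: str) -> int:
        """+1 up, -1 down, 0 not called (or absent)."""
        if gene in self.up_genes:
            return 1
        if gene in self.down_genes:
            return -1
        return 0


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths (bp).

    Per sample: rpk = count / (length/1000); tpm = rpk * 1e6 / sum(rpk).
    Columns of the result sum to 1e6.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"genes without length annotation: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rpk = counts.div(lengths / 1000.0, axis=0)
    per_sample = rpk.sum(axis=0)
    zero = per_sample.index[per_sample == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has all-zero counts")
    return rpk.div(per_sample, axis=1) * 1e6


def is_expressed(mean_tpm: pd.Series, threshold: float = 1.0) -> pd.Series:
    """Strict gate: a gene is expressed iff its mean TPM exceeds ``threshold``.

    Exactly 1 TPM is *not* expressed under the default gate.
    """
    return mean_tpm > threshold


def population_mean(expr: PopulationExpression, population: str) -> pd.Series:
    """Arithmetic per-gene mean over a population's replicates."""
    samples = expr.samples_of(population)
    if not samples:
        raise ValueError(f"population {population!r} has no samples")
    return expr.values[samples].mean(axis=1)


def select_lipid_panel(
    de_comparisons: list[DEComparison],
    gene_panel: list[str],
    min_hits: int = 3,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Heat-map matrix of log2FC for panel genes recurrently significant.

    A panel gene is retained iff its adjusted p is below
    ``padj_threshold`` in at least ``min_hits`` of the comparisons; the
    returned frame holds log2FC values (genes x comparisons) for the
    retained genes.
    """
    if not gene_panel:
        raise ValueError("gene panel is empty")
    if not de_comparisons:
        raise ValueError("no DE comparisons supplied")
    panel = list(dict.fromkeys(gene_panel))
    hits = pd.Series(0, index=panel)
    lfc = {}
    for de in de_comparisons:
        sub = de.table.reindex(panel)
        hits += (sub["padj"] < padj_threshold).fillna(False).astype(int)
        lfc[de.comparison] = sub["log2fc"]
    keep = hits.index[hits >= min_hits]
    return pd.DataFrame(lfc).loc[keep]
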