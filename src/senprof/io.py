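"""Readers and writers for the pipeline's on-disk formats.

TSV for matrices, annotations, DE tables, regulons and scaffolds; GMT
for gene-set collections; BED6 plus a counts TSV for ATAC peaks; JSON
for run manifests. Every writer/reader pair round-trips valid data
losslessly. Genomic coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expression import DEComparison, PopulationExpression, ANNOTATION_FIELDS
from .atac import PeakTable

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "read_scaffold",
    "read_edge_list",
    "read_bed_peaks",
    "write_bed_peaks",
    "write_manifest",
]


class FormatError(ValueError):
    """Malformed input file."""


def read_expression(
    matrix_path: str | Path, annotation_path: str | Path, unit: str = "tpm"
) -> PopulationExpression:
    """Load a genes x samples TSV plus its sample-annotation TSV.

    The matrix needs a ``gene`` index column and a ``length`` column of
    gene lengths in bp; annotations are indexed by sample id with the
    cell_type/state/timepoint/age/replicate columns.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {matrix_path}")
    if "length" not in mat.columns:
        raise FormatError(f"{matrix_path}: missing 'length' column")
    lengths = mat.pop("length")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    if not set(ANNOTATION_FIELDS) <= set(ann.columns):
        raise FormatError(
            f"{annotation_path}: annotation needs columns {ANNOTATION_FIELDS}"
        )
    unlabelled = set(mat.columns) - set(ann.index)
    if unlabelled:
        raise FormatError(
            f"samples without annotation: {sorted(unlabelled)[:5]}"
        )
    return PopulationExpression(mat, ann, lengths, unit=unit)


def write_expression(expr: PopulationExpression, matrix_path, annotation_path) -> None:
    out = expr.values.copy()
    out.insert(0, "length", expr.gene_lengths.reindex(out.index))
    out.to_csv(matrix_path, sep="\t", float_format="%.6g")
    expr.annotations.to_csv(annotation_path, sep="\t")


def read_de_table(path: str | Path, comparison: str | None = None) -> DEComparison:
    table = pd.read_csv(path, sep="\t", index_col=0)
    need = {"log2fc", "pvalue", "padj"}
    if not need <= set(table.columns):
        raise FormatError(
            f"{path}: DE table missing columns {sorted(need - set(table.columns))}"
        )
    return DEComparison(comparison or Path(path).stem, table)


def write_de_table(de: DEComparison, path: str | Path) -> None:
    de.table.to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name, description, members (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    ">=1 member"
                )
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, "na"] + sorted(gene_sets[name])) + "\n")


def read_regulons(path: str | Path) -> pd.DataFrame:
    """Signed regulon TSV with columns tf, target, sign, source."""
    reg = pd.read_csv(path, sep="\t", dtype={"sign": str})
    need = {"tf", "target", "sign"}
    if not need <= set(reg.columns):
        raise FormatError(f"{path}: regulon table needs columns {sorted(need)}")
    try:
        signs = reg["sign"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer regulon sign") from exc
    bad = signs[~signs.isin((1, -1))]
    if len(bad):
        raise FormatError(
            f"{path}: regulon sign must be +1 or -1, got {bad.iloc[0]}"
        )
    reg["sign"] = signs
    if "source" not in reg.columns:
        reg["source"] = "unknown"
    if reg.duplicated(["tf", "target", "source"]).any():
        raise FormatError(f"{path}: duplicate (tf, target) within one source")
    return reg


def read_scaffold(path: str | Path) -> pd.DataFrame:
    sc = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(sc.columns):
        raise FormatError(f"{path}: scaffold needs ligand and receptor columns")
    return sc.drop_duplicates(["ligand", "receptor"]).reset_index(drop=True)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    if not {"source", "target"} <= set(edges.columns):
        raise FormatError(f"{path}: edge list needs source and target columns")
    return edges


def read_bed_peaks(
    bed_path: str | Path, counts_path: str | Path | None = None
) -> PeakTable:
    """BED6 peaks (0-based half-open) with an optional counts TSV.

    The BED name field is the peak id; the counts TSV is indexed by
    peak id with per-sample columns plus optional annotation/gene/tss
    metadata columns. Without counts the skeleton carries zero counts
    for a single placeholder sample.
    """
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{bed_path}:{lineno}: BED needs >=4 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{bed_path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise FormatError(f"{bed_path}:{lineno}: end <= start")
            rows.append(
                {
                    "peak_id": parts[3],
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                }
            )
    meta = pd.DataFrame(rows).set_index("peak_id")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise FormatError(f"{bed_path}: duplicate peak id {dup!r}")
    meta["annotation"] = ""
    meta["gene"] = ""
    meta["tss"] = float("nan")
    if counts_path is None:
        counts = pd.DataFrame({"placeholder": 0}, index=meta.index)
        groups = pd.Series({"placeholder": "none"})
        return PeakTable(meta, counts, groups)
    extra = pd.read_csv(counts_path, sep="\t", index_col=0)
    for col in ("annotation", "gene", "tss"):
        if col in extra.columns:
            meta[col] = extra.pop(col)
    counts = extra.reindex(meta.index)
    if counts.isna().any().any():
        raise FormatError(f"{counts_path}: counts missing for some peaks")
    groups = pd.Series({s: s.split(".")[1] if "." in s else "all" for s in counts.columns})
    return PeakTable(meta, counts, groups)


def write_bed_peaks(peaks: PeakTable, bed_path, counts_path) -> None:
    meta = peaks.meta
    bed = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "start": meta["start"],
            "end": meta["end"],
            "name": meta.index,
            "score": 0,
            "strand": "+",
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    out = meta[["annotation", "gene", "tss"]].join(peaks.counts)
    out.to_csv(counts_path, sep="\t", float_format="%.6g")


def write_manifest(path: str | Path, stage: str, inputs: dict, config: dict, seed) -> None:
    """Deterministic JSON provenance record (no timestamps)."""
    payload = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in sorted(inputs.items())},
        "config": config,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
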