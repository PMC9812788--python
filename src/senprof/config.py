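"""Run configuration with the study's printed defaults.

Every threshold is overridable from a flat ``key = value`` text file
or CLI flags; the defaults are the values the analysis protocol
states: a strict 1 TPM expression gate, 100 permutations with a
mean + 2 s.d. significance rule, adjusted p < 0.05 for DE calls,
GSEA-style FDR < 0.25 recurrence, >= 8 of 12 comparisons, average
trust strictly > 1, quartile score >= 2, 2,000 SPIA bootstraps with
pGFdr < 0.05, ATAC signal > 5 with |log2FC| > 1 inside TSS +- 1 kb
promoters, and GO term sizes strictly between 15 and 500.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    tpm_expressed: float = 1.0
    n_permutations: int = 100
    sd_multiplier: float = 2.0
    de_padj: float = 0.05
    gsea_fdr: float = 0.25
    min_comparisons: int = 8
    total_comparisons: int = 12
    trust_min: float = 1.0  # strict ">"
    score_min: int = 2
    spia_nboot: int = 2000
    spia_fdr: float = 0.05
    atac_min_signal: float = 5.0
    atac_lfc: float = 1.0
    atac_peak_padj: float = 0.1
    promoter_halfwidth: int = 1000
    term_size_min: int = 15
    term_size_max: int = 500
    reach_threshold: float = 0.1
    lipid_min_hits: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")
        if self.min_comparisons > self.total_comparisons:
            raise ValueError(
                "min_comparisons must not exceed total_comparisons"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file (``#`` starts a comment)."""
    overrides: dict[str, object] = {}
    types = {f.name: f.type for f in fields(RunConfig)}
    casts = {"int": int, "float": float}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            overrides[key] = casts[types[key]](value)
    return RunConfig(**overrides)
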