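"""Per-domain and whole-model aggregation of predictor confidence scores.

Structure predictors emit a per-residue pLDDT (0–100, stored in the
B-factor column); for a multi-subdomain target the informative summaries
are per-domain means — a model can be confidently predicted at the domain
level while the domain *packing* (which pTM addresses, 0–1) is uncertain.

Interpretation bands: >90 high accuracy; 70–90 moderate to good;
50–70 low confidence; <50 disordered. Boundary scores are assigned to the
higher band (90 → high, 70 → moderate, 50 → low).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structure_io import ResidueId

__all__ = [
    "ConfidenceTable",
    "domain_plddt",
    "summarize_models",
    "classify_confidence",
]

_BANDS = (
    (90.0, "high"),
    (70.0, "moderate"),
    (50.0, "low"),
)


@dataclass
class ConfidenceTable:
    """Per-domain mean pLDDT rows plus the Whole-model mean.

    ``ptm`` is pass-through metadata (predictors report it alongside the
    model; it is never computed here).
    """

    rows: Dict[str, float]  # domain name (and "Whole") → mean pLDDT
    counts: Dict[str, int]  # residues contributing per row
    ptm: Optional[float] = None
    bands: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bands:
            self.bands = {k: classify_confidence(v) for k, v in self.rows.items()}

    def to_tsv(self) -> str:
        lines = ["domain\tmean_plddt\tn_residues\tband"]
        for name, v in self.rows.items():
            lines.append(f"{name}\t{v:.1f}\t{self.counts[name]}\t{self.bands[name]}")
        if self.ptm is not None:
            lines.append(f"pTM\t{self.ptm:.2f}\t\t")
        return "\n".join(lines) + "\n"


def domain_plddt(
    scores: Dict[ResidueId, float],
    domains: Dict[str, List[ResidueId]],
    ptm: Optional[float] = None,
) -> ConfidenceTable:
    """Arithmetic mean pLDDT per domain and over the whole model.

    ``domains`` is the residue partition from
    :func:`pocketgauge.structure_io.assign_domains`. Domains with no scored
    residues are omitted with a warning. The Whole row is the mean over
    every scored residue, which equals the residue-count-weighted mean of
    the domain rows.
    """
    if not scores:
        raise ValueError("empty score map")
    rows: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for name, rids in domains.items():
        vals = [scores[rid] for rid in rids if rid in scores]
        if not vals:
            if rids:
                warnings.warn(f"domain {name!r}: no scored residues; row omitted")
            continue
        rows[name] = float(np.mean(vals))
        counts[name] = len(vals)
    assigned = {rid for rids in domains.values() for rid in rids}
    whole_vals = [v for rid, v in scores.items() if rid in assigned]
    if not whole_vals:
        whole_vals = list(scores.values())
    rows["Whole"] = float(np.mean(whole_vals))
    counts["Whole"] = len(whole_vals)
    return ConfidenceTable(rows=rows, counts=counts, ptm=ptm)


def summarize_models(
    whole_scores: Sequence[float],
    std_kind: str = "population",
) -> Tuple[float, Optional[float]]:
    """Mean and spread of whole-model scores across a set of models.

    ``std_kind='population'`` divides by n (ddof=0), ``'sample'`` by n−1.
    Published summaries do not always say which they used, so both are one
    keyword away. With fewer than 2 models the std is ``None``.
    """
    if std_kind not in ("population", "sample"):
        raise ValueError(f"unknown std kind {std_kind!r}")
    vals = np.asarray(list(whole_scores), dtype=float)
    if vals.size == 0:
        raise ValueError("no model scores supplied")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None
    std = float(vals.std(ddof=0 if std_kind == "population" else 1))
    return mean, std


def classify_confidence(score: float) -> str:
    """Band label for a 0–100 confidence score (boundary → higher band)."""
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    for cut, label in _BANDS:
        if score >= cut:
            return label
    return "disordered"
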