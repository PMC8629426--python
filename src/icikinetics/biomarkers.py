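"""Mapping of fitted model parameters to histopathology-scale biomarkers.

The immune state Lambda is converted to an intratumoral CD8+ T-cell density by
assuming each CD8+ cell kills one tumor cell on average and a tumor
microenvironment density of 5558 cells/mm^2 (quantitatively measured in
melanoma), so density = Lambda * 5558. The immunotherapy effect mu maps to a
PD-L1 positivity percentage as mu * 100; negative fitted mu (possible in
validation-style cohorts) is reported raw but clamped at 0 for stratification,
since staining percentages cannot be negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .fitting import FitResult
from .response import ResponseLabel

__all__ = [
    "CD8_DENSITY_PER_LAMBDA",
    "LITERATURE_ORR",
    "BiomarkerEstimate",
    "OrrByCutoff",
    "lambda_to_cd8",
    "mu_to_pdl1_percent",
    "pdl1_stratum",
    "orr_by_cutoff",
    "biomarker_table",
]

#: Tumor-microenvironment cell density used in the Lambda -> CD8 conversion
#: (cells/mm^2), with an assumed one-kill-per-cell immune fitness.
CD8_DENSITY_PER_LAMBDA = 5558.0

#: Pooled literature objective response rates by PD-L1 staining cutoff,
#: used only as report annotations (fractions; n = pooled patients).
LITERATURE_ORR = {
    1.0: {"below": 0.15, "at_or_above": 0.28, "n": 975},
    5.0: {"below": 0.21, "at_or_above": 0.38, "n": 1492},
}


@dataclass(frozen=True)
class BiomarkerEstimate:
    """Histopathology-scale view of one patient's fitted parameters."""

    patient_id: str
    cd8_density: float  # cells/mm^2
    pdl1_percent: float  # raw, may be negative
    stratum_1pct: str  # "<1%" | ">=1%"
    stratum_5pct: str  # "<5%" | ">=5%"


def lambda_to_cd8(lam: float, density: float = CD8_DENSITY_PER_LAMBDA) -> float:
    """Estimated intratumoral CD8+ T-cell density (cells/mm^2) from Lambda."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    return lam * density


def mu_to_pdl1_percent(mu: float) -> float:
    """PD-L1 positivity (%) from mu; raw value, no clamping."""
    if not math.isfinite(mu):
        raise ValueError("mu must be finite")
    return mu * 100.0


def pdl1_stratum(mu: float, cutoff_percent: float) -> str:
    """Stratum label at a PD-L1 cutoff; negative percentages clamp to 0."""
    pct = max(0.0, mu_to_pdl1_percent(mu))
    return f">={cutoff_percent:g}%" if pct >= cutoff_percent else f"<{cutoff_percent:g}%"


@dataclass(frozen=True)
class OrrByCutoff:
    """Objective response rate within each PD-L1 stratum at one cutoff."""

    cutoff_percent: float
    n_below: int
    n_at_or_above: int
    orr_below: float  # NaN when the stratum is empty
    orr_at_or_above: float


def orr_by_cutoff(
    fits: Sequence[FitResult],
    labels: Mapping[str, bool] | Sequence[ResponseLabel],
    cutoff_percent: float,
) -> OrrByCutoff:
    """ORR (fraction favorable) below vs at/above a PD-L1-style mu cutoff.

    Every fitted patient must carry a response label. Empty strata yield
    NaN with a warning rather than a silent 0.
    """
    if not isinstance(labels, Mapping):
        labels = {l.patient_id: l.favorable for l in labels}
    below, above = [], []
    for f in fits:
        if f.patient_id not in labels:
            raise ValueError(f"no response label for patient {f.patient_id!r}")
        fav = bool(labels[f.patient_id])
        pct = max(0.0, mu_to_pdl1_percent(f.mu))
        (above if pct >= cutoff_percent else below).append(fav)

    def _orr(group: list[bool], name: str) -> float:
        if not group:
            warnings.warn(
                f"ORR undefined: empty {name} stratum at {cutoff_percent:g}%",
                stacklevel=3,
            )
            return math.nan
        return sum(group) / len(group)

    return OrrByCutoff(
        cutoff_percent=float(cutoff_percent),
        n_below=len(below),
        n_at_or_above=len(above),
        orr_below=_orr(below, "below-cutoff"),
        orr_at_or_above=_orr(above, "at-or-above-cutoff"),
    )


def biomarker_estimate(fit: FitResult) -> BiomarkerEstimate:
    return BiomarkerEstimate(
        patient_id=fit.patient_id,
        cd8_density=lambda_to_cd8(fit.lam),
        pdl1_percent=mu_to_pdl1_percent(fit.mu),
        stratum_1pct=pdl1_stratum(fit.mu, 1.0),
        stratum_5pct=pdl1_stratum(fit.mu, 5.0),
    )


def biomarker_table(
    fits: Sequence[FitResult],
    labels: Mapping[str, bool] | Sequence[ResponseLabel] | None = None,
) -> pd.DataFrame:
    """Per-patient biomarker CSV table (fixed column order)."""
    if labels is not None and not isinstance(labels, Mapping):
        labels = {l.patient_id: l.favorable for l in labels}
    rows = []
    for f in fits:
        est = biomarker_estimate(f)
        rows.append(
            {
                "patient_id": f.patient_id,
                "lambda": f.lam,
                "cd8_density": est.cd8_density,
                "mu": f.mu,
                "pdl1_percent": est.pdl1_percent,
                "stratum_1pct": est.stratum_1pct,
                "stratum_5pct": est.stratum_5pct,
                "favorable": (
                    bool(labels[f.patient_id]) if labels is not None else pd.NA
                ),
            }
        )
    return pd.DataFrame(rows)
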