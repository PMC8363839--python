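"""Scalar membrane descriptors and dose-effect trend checks.

Area per lipid is the lateral box area divided by the lipid count per
leaflet; mean thickness is the area-weighted average of the thickness
field.  ``dose_trend_report`` verifies the strict orderings expected for a
dose series of an intercalating additive (thickness decreasing, area per
lipid increasing with dose).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .fields import Field2D
from .surface import CurvatureSummary
from .diffusion import DiffusionResults
from .trajectory import Frame


def area_per_lipid(frame_or_box, lipids_per_leaflet: int) -> float:
    """Lx * Ly / lipids_per_leaflet in nm^2.

    ``frame_or_box`` is a :class:`Frame` or any (Lx, Ly[, Lz]) sequence in
    nm; only the lateral box lengths enter.
    """
    if lipids_per_leaflet <= 0:
        raise ParameterError("lipids_per_leaflet must be positive")
    box = frame_or_box.box if isinstance(frame_or_box, Frame) else frame_or_box
    lx, ly = float(box[0]), float(box[1])
    if lx <= 0 or ly <= 0:
        raise ParameterError("box lengths must be positive")
    return lx * ly / lipids_per_leaflet


def mean_thickness(field: Field2D) -> float:
    """Area-weighted mean of a thickness field in nm (uniform cells)."""
    if field.kind != "thickness":
        raise ParameterError(f"expected a thickness field, got {field.kind!r}")
    return float(field.values.mean())


@dataclass
class ConditionSummary:
    """Per-condition membrane descriptors (one simulated/measured system)."""

    label: str
    apl: Optional[float] = None                 # nm^2
    mean_thickness: Optional[float] = None      # nm
    footprint: Optional[CurvatureSummary] = None
    D: Optional[DiffusionResults] = None

    def __post_init__(self):
        if self.apl is not None and self.apl <= 0:
            raise ParameterError("area per lipid must be positive")
        if self.mean_thickness is not None and self.mean_thickness <= 0:
            raise ParameterError("mean thickness must be positive")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "apl_nm2": self.apl,
            "mean_thickness_nm": self.mean_thickness,
            "footprint": self.footprint.to_dict() if self.footprint else None,
            "diffusion": self.D.to_dict() if self.D else None,
        }


_METRIC_GETTERS = {
    "apl": lambda s: s.apl,
    "mean_thickness": lambda s: s.mean_thickness,
    "footprint_abs": lambda s: s.footprint.footprint_abs if s.footprint else None,
    "D": lambda s: s.D.D if s.D else None,
}


def dose_trend_report(summaries: Sequence[ConditionSummary],
                      expected_order: dict, tol: float = 0.0) -> dict:
    """Check strict per-metric orderings across conditions.

    ``expected_order`` maps a metric name (``apl``, ``mean_thickness``,
    ``footprint_abs``, ``D``) to the list of condition labels expected in
    *increasing* order of that metric, e.g.
    ``{"mean_thickness": ["48TFP", "24TFP", "0TFP"],
    "apl": ["0TFP", "24TFP", "48TFP"]}``.  Each consecutive pair must
    increase by more than ``tol`` (default 0: strict inequality).  Returns a
    machine-readable dict with a pass/fail verdict and the observed ordering
    per metric.
    """
    if len(summaries) < 2:
        raise ParameterError("trend checks need at least two conditions")
    labels = [s.label for s in summaries]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate condition labels in {labels}")
    by_label = {s.label: s for s in summaries}

    report = {"conditions": labels, "tolerance": tol, "metrics": {}}
    for metric, order in expected_order.items():
        if metric not in _METRIC_GETTERS:
            raise ParameterError(f"unknown metric {metric!r}")
        missing = [lab for lab in order if lab not in by_label]
        if missing:
            raise ParameterError(f"labels {missing} not among the conditions")
        get = _METRIC_GETTERS[metric]
        values = {lab: get(by_label[lab]) for lab in order}
        if any(v is None for v in values.values()):
            raise ParameterError(f"metric {metric!r} missing for some condition")
        seq = [values[lab] for lab in order]
        ok = all(b - a > tol for a, b in zip(seq, seq[1:]))
        observed = sorted(order, key=lambda lab: values[lab])
        report["metrics"][metric] = {
            "expected_increasing": list(order),
            "observed_increasing": observed,
            "values": {lab: float(values[lab]) for lab in order},
            "pass": bool(ok),
        }
    report["all_pass"] = all(m["pass"] for m in report["metrics"].values())
    return report


def condition_table(summaries: Sequence[ConditionSummary]) -> "object":
    """Aggregate comparison table as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for s in summaries:
        rows.append({
            "label": s.label,
            "apl_nm2": s.apl,
            "mean_thickness_nm": s.mean_thickness,
            "footprint_mean_nm^-1": s.footprint.footprint_mean if s.footprint else np.nan,
            "footprint_abs_nm^-1": s.footprint.footprint_abs if s.footprint else np.nan,
            "D_cm2_s": s.D.D if s.D else np.nan,
            "D_error_cm2_s": s.D.D_error if s.D else np.nan,
        })
    return pd.DataFrame(rows)
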