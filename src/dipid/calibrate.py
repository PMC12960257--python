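"""Heuristic two-regime calibration of naive diameter predictions.

Measured container and tube diameters deviate from the naive wedge-model
prediction with a nearly linear trend whose slope changes between small
and large structures, so the refinement is a continuous piecewise-linear
map with a single breakpoint,

    d_cal = c0 + c1 * d_naive + c2 * max(0, d_naive - b),

fitted separately for containers and tubes.  For a fixed breakpoint the
model is linear in (c0, c1, c2); the breakpoint itself is chosen by an
exhaustive 1-D scan minimizing the total squared residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationModel", "fit_calibration", "calibrate_diameter"]


@dataclass(frozen=True)
class CalibrationModel:
    kind: str  # "container" or "tube"
    breakpoint: float  # nm
    intercept: float
    slope_low: float
    slope_high: float

    def __post_init__(self) -> None:
        if self.kind not in ("container", "tube"):
            raise ValueError(f"kind must be 'container' or 'tube', got {self.kind!r}")

    def __call__(self, d_naive):
        return calibrate_diameter(d_naive, self)

    @property
    def is_monotone(self) -> bool:
        return self.slope_low > 0 and self.slope_high > 0


def calibrate_diameter(d_naive, model: CalibrationModel):
    """Apply the piecewise-linear calibration map (continuous at the breakpoint)."""
    d = np.asarray(d_naive, dtype=float)
    out = (model.intercept + model.slope_low * d
           + (model.slope_high - model.slope_low) * np.maximum(0.0, d - model.breakpoint))
    return float(out) if np.isscalar(d_naive) else out


def fit_calibration(pairs, kind: str, breakpoint_step: float = 10.0) -> CalibrationModel:
    """Least-squares fit of the two-regime map to (d_naive, d_measured) pairs.

    Parameters
    ----------
    pairs : sequence of (float, float)
        Naive and measured diameters, nm.  At least four pairs are needed
        (three linear coefficients plus the breakpoint), spanning both
        regimes.
    kind : str
        "container" or "tube"; stored on the model for provenance.
    breakpoint_step : float
        Resolution of the exhaustive breakpoint scan, nm.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise ValueError("need at least 4 (d_naive, d_measured) pairs")
    x, y = arr[:, 0], arr[:, 1]
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("pairs must span a range of naive diameters")
    candidates = np.arange(lo + breakpoint_step, hi, breakpoint_step)
    if candidates.size == 0:
        candidates = np.array([0.5 * (lo + hi)])

    best = None
    for b in candidates:
        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - b)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ coef - y) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, b, coef)
    _, b, (c0, c1, c2) = best
    return CalibrationModel(kind=kind, breakpoint=float(b), intercept=float(c0),
                            slope_low=float(c1), slope_high=float(c1 + c2))
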