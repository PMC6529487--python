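"""Tissue-to-plasma ratio time courses, bound comparison and classification.

The tissue-to-plasma (t/p) ratio — organ activity concentration divided
by the plasma concentration at the same decay-corrected time — tracks
tracer extravasation.  It is bracketed by the physiological bounds of
:mod:`albupet.physiology`: ``tp_min`` when the tracer stays vascular,
``tp_max`` when the interstitium has equilibrated with plasma.  Each
organ trajectory is classified into the qualitative groups a
biodistribution read-out distinguishes:

* ``vascular-confined`` — flat at tp_min (blood-brain barrier);
* ``rapid-equilibration`` — at tp_max from the first scan on (leaky or
  fenestrated endothelium: lung, liver, spleen);
* ``increasing`` — monotone rise between the bounds (slow
  extravasation: muscle, parotid gland, pancreas, bone marrow);
* ``exceeds-maximum`` — above tp_max (blood-pool contamination of the
  VoI, or residualizing-label accumulation: heart, kidney).

Since only a handful of scan times exist, the trend test is a rank
correlation plus a pairwise non-decrease check, not a fitted slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .physiology import TPBounds

__all__ = [
    "TPTrajectory",
    "UndefinedRatioError",
    "InsufficientDataError",
    "tp_ratio",
    "interpolate_plasma",
    "classify_trajectory",
    "build_trajectory",
    "CLASSIFICATIONS",
]

CLASSIFICATIONS = (
    "vascular-confined",
    "rapid-equilibration",
    "increasing",
    "exceeds-maximum",
    "unclassified",
)


class UndefinedRatioError(ValueError):
    """Raised when the plasma reference concentration is not positive."""


class InsufficientDataError(ValueError):
    """Raised when a trajectory has fewer than three valid ratios."""


@dataclass
class TPTrajectory:
    """One organ's t/p ratio time course with its theoretical bounds."""

    organ_name: str
    times: np.ndarray
    tp: np.ndarray
    tp_min: float
    tp_max: float
    classification: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tp = np.asarray(self.tp, dtype=float)
        if self.times.shape != self.tp.shape:
            raise ValueError("times and tp must match in shape")
        if np.any(self.tp < 0):
            raise ValueError("t/p ratios must be non-negative")
        if not 0 <= self.tp_min <= self.tp_max:
            raise ValueError("invalid bounds")


def tp_ratio(tissue_conc, plasma_conc):
    """tissue / plasma concentration ratio (both decay-corrected).

    Accepts scalars or arrays; identical whether the inputs are raw
    concentrations or SUVs, since the SUV normalization cancels.
    """
    plasma = np.asarray(plasma_conc, dtype=float)
    if np.any(plasma <= 0):
        raise UndefinedRatioError("plasma concentration must be positive")
    return np.asarray(tissue_conc, dtype=float) / plasma


def interpolate_plasma(times, concentrations, at_times):
    """Log-linear interpolation of a plasma curve to scan times.

    Exact at sample points; falls back to linear interpolation across
    zero-valued samples.  Scan times outside the sampled range raise.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    at = np.atleast_1d(np.asarray(at_times, dtype=float))
    if np.any(at < t[0]) or np.any(at > t[-1]):
        raise ValueError("scan time outside the sampled plasma range")
    if np.all(c > 0):
        return np.exp(np.interp(at, t, np.log(c)))
    return np.interp(at, t, c)


def classify_trajectory(traj: TPTrajectory, tol: float = 0.2) -> str:
    """Deterministic classification of a t/p trajectory against its bounds.

    Rule order (first match wins), with relative tolerance ``tol``:

    1. any tp > tp_max*(1+tol)            -> "exceeds-maximum"
    2. all tp <= tp_min*(1+tol)           -> "vascular-confined"
    3. first tp >= tp_max*(1-tol)         -> "rapid-equilibration"
    4. positive rank correlation with time and no successive relative
       decrease beyond tol               -> "increasing"
    5. otherwise                          -> "unclassified"
    """
    if traj.tp.size < 3:
        raise InsufficientDataError("need at least three time points to classify")
    tp = traj.tp
    if np.any(tp > traj.tp_max * (1 + tol)):
        return "exceeds-maximum"
    if np.all(tp <= traj.tp_min * (1 + tol)):
        return "vascular-confined"
    if tp[0] >= traj.tp_max * (1 - tol):
        return "rapid-equilibration"
    rho = stats.spearmanr(traj.times, tp).statistic
    rel_steps = np.diff(tp) / np.maximum(tp[:-1], 1e-300)
    if rho > 0 and np.all(rel_steps >= -tol):
        return "increasing"
    return "unclassified"


def build_trajectory(
    organ_name: str,
    times,
    tissue_conc,
    plasma_conc,
    bounds: TPBounds,
    tol: float = 0.2,
) -> TPTrajectory:
    """Assemble and classify a trajectory from matched tissue/plasma values."""
    traj = TPTrajectory(
        organ_name=organ_name,
        times=np.asarray(times, dtype=float),
        tp=tp_ratio(tissue_conc, plasma_conc),
        tp_min=bounds.tp_min,
        tp_max=bounds.tp_max,
    )
    traj.classification = classify_trajectory(traj, tol=tol)
    return traj
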