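"""Non-compartmental analysis (NCA) of plasma concentration-time curves.

Model-agnostic estimation of the standard parameter set — Cmax, AUC,
terminal rate constant (lambda_z), half-life, clearance, AUMC, mean
residence time and steady-state volume — plus cohort summarization and
a leave-one-out outlier screen for cross-subject sampling points.

Conventions (spelled out because every NCA implementation differs in
the details):

* AUC/AUMC use the linear-up/log-down trapezoid: logarithmic
  interpolation on strictly decreasing positive segments (exact on
  exponential declines), linear elsewhere.
* lambda_z is fitted by log-linear least squares on the terminal
  points; the window is chosen among all suffixes of the post-Tmax
  points (at least 3 points, Tmax itself excluded) by maximizing the
  adjusted R^2, ties resolved in favour of more points.
* Extrapolation: AUC(0-inf) = AUC(0-last) + C_last/lambda_z, and
  AUMC(0-inf) = AUMC(0-last) + C_last*t_last/lambda_z + C_last/lambda_z^2,
  with C_last the last observed positive concentration.
* MRT subtracts half the infusion duration for zero-order input;
  Vss = CL * MRT.
* Cohort statistics use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .simulate.types import PlasmaCurve

__all__ = [
    "NCAResult",
    "CohortSummary",
    "NonEstimableError",
    "fit_lambda_z",
    "compute_auc",
    "nca",
    "screen_outliers",
    "summarize_cohort",
]

NCA_PARAMETERS = (
    "cmax",
    "tmax",
    "auc_0_last",
    "auc_0_inf",
    "pct_extrapolated",
    "lambda_z",
    "half_life",
    "clearance",
    "aumc_0_inf",
    "mrt",
    "vss",
    "v_initial",
)


class NonEstimableError(ValueError):
    """Raised when the terminal phase cannot be estimated from the data."""


@dataclass(frozen=True)
class NCAResult:
    """The full non-compartmental parameter set for one subject."""

    subject_id: str
    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_last: float  # ng*h/mL
    auc_0_inf: float  # ng*h/mL
    pct_extrapolated: float  # %
    lambda_z: float  # 1/h
    half_life: float  # h
    clearance: float  # mL/h
    aumc_0_inf: float  # ng*h^2/mL
    mrt: float  # h
    vss: float  # mL
    v_initial: float  # mL (dose / Cmax)
    n_lambda_points: int
    lambda_fit_r2adj: float
    extrapolation_warning: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CohortSummary:
    """Min/max/median/mean/sample-SD per NCA parameter across subjects."""

    table: pd.DataFrame  # index: parameter; columns: min, max, median, mean, stdev
    n_subjects: int
    single_subject: bool = False


def _loglinear_fit(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and adjusted R^2 of logc vs t."""
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), float(r2adj)


def fit_lambda_z(curve: PlasmaCurve, min_points: int = 3) -> tuple[float, float, int]:
    """Terminal log-linear rate constant of one curve.

    Returns ``(lambda_z, r2adj, n_points)``.  Candidate windows are the
    suffixes of the strictly-post-Tmax positive-concentration points
    with at least ``min_points`` points; the window with the highest
    adjusted R^2 wins, ties (within 1e-12) going to the longer window.

    Raises NonEstimableError when no window yields a positive slope
    magnitude.
    """
    t, c = curve.times, curve.concentrations
    imax = int(np.argmax(c))
    sel = (np.arange(t.size) > imax) & (c > 0)
    t_tail, c_tail = t[sel], c[sel]
    if t_tail.size < min_points:
        raise NonEstimableError(
            f"need >= {min_points} positive post-Tmax points, have {t_tail.size}"
        )
    logc = np.log(c_tail)
    best: tuple[float, int, float] | None = None  # (r2adj, n, lambda_z)
    for start in range(t_tail.size - min_points + 1):
        slope, _, r2adj = _loglinear_fit(t_tail[start:], logc[start:])
        lam = -slope
        if lam <= 0:
            continue
        n = t_tail.size - start
        if best is None or r2adj > best[0] + 1e-12 or (abs(r2adj - best[0]) <= 1e-12 and n > best[1]):
            best = (r2adj, n, lam)
    if best is None:
        raise NonEstimableError("no terminal window with a declining log-linear fit")
    r2adj, n, lam = best
    return lam, r2adj, n


def compute_auc(curve: PlasmaCurve) -> tuple[float, float]:
    """AUC(0-last) and AUMC(0-last) by the linear-up/log-down rule."""
    t, c = curve.times, curve.concentrations
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.any(c < 0):
        raise ValueError("negative concentrations")
    auc = 0.0
    aumc = 0.0
    for i in range(t.size - 1):
        t0, t1, c0, c1 = t[i], t[i + 1], c[i], c[i + 1]
        dt = t1 - t0
        if c0 > c1 > 0:
            k = math.log(c0 / c1) / dt
            auc += (c0 - c1) / k
            aumc += (t0 * c0 - t1 * c1) / k + (c0 - c1) / k**2
        else:
            auc += (c0 + c1) * dt / 2.0
            aumc += (t0 * c0 + t1 * c1) * dt / 2.0
    return float(auc), float(aumc)


def nca(
    curve: PlasmaCurve,
    dose: float,
    infusion_duration: float = 0.0,
    extrapolation_cap_pct: float = 20.0,
) -> NCAResult:
    """Full non-compartmental parameter set for one screened curve.

    ``dose`` must be in units consistent with the curve (ng for a
    total-protein curve in ng/mL, Bq for a radio curve in Bq/mL); the
    clearance and volume results then come out in mL/h and mL.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    t, c = curve.times, curve.concentrations
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    lam, r2adj, n_lam = fit_lambda_z(curve)
    auc_last, aumc_last = compute_auc(curve)
    pos = np.nonzero(c > 0)[0]
    c_last, t_last = float(c[pos[-1]]), float(t[pos[-1]])
    auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_last + c_last * t_last / lam + c_last / lam**2
    pct_extra = 100.0 * (auc_inf - auc_last) / auc_inf
    clearance = dose / auc_inf
    mrt = aumc_inf / auc_inf - infusion_duration / 2.0
    warn = pct_extra > extrapolation_cap_pct
    if warn:
        warnings.warn(
            f"{curve.subject_id}: {pct_extra:.1f}% of AUC extrapolated "
            f"(cap {extrapolation_cap_pct}%)",
            stacklevel=2,
        )
    return NCAResult(
        subject_id=curve.subject_id,
        cmax=cmax,
        tmax=tmax,
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        pct_extrapolated=pct_extra,
        lambda_z=lam,
        half_life=math.log(2.0) / lam,
        clearance=clearance,
        aumc_0_inf=aumc_inf,
        mrt=mrt,
        vss=clearance * mrt,
        v_initial=dose / cmax,
        n_lambda_points=n_lam,
        lambda_fit_r2adj=r2adj,
        extrapolation_warning=warn,
    )


def screen_outliers(
    curves: list[PlasmaCurve],
    threshold_sd: float = 5.0,
    min_subjects: int = 3,
) -> list[tuple[str, float]]:
    """Leave-one-out outlier screen across a cohort.

    At each time point sampled by at least ``min_subjects`` subjects,
    a sample is flagged when it deviates from the mean of the *other*
    subjects' values by more than ``threshold_sd`` of their sample
    standard deviation.  Returns ``(subject_id, time)`` pairs; callers
    drop the flagged samples before NCA.
    """
    by_time: dict[float, list[tuple[str, float]]] = {}
    for curve in curves:
        for t, c in zip(curve.times, curve.concentrations):
            by_time.setdefault(float(t), []).append((curve.subject_id, float(c)))
    flagged: list[tuple[str, float]] = []
    for t, samples in sorted(by_time.items()):
        if len(samples) < min_subjects:
            warnings.warn(
                f"t={t} h: only {len(samples)} subject(s); outlier screen skipped",
                stacklevel=2,
            )
            continue
        values = np.array([v for _, v in samples])
        for i, (sid, v) in enumerate(samples):
            others = np.delete(values, i)
            sd = others.std(ddof=1)
            if sd == 0:
                continue
            if abs(v - others.mean()) > threshold_sd * sd:
                flagged.append((sid, t))
    return flagged


def drop_flagged(curve: PlasmaCurve, flagged: list[tuple[str, float]]) -> PlasmaCurve:
    """Remove a subject's flagged time points from its curve."""
    bad_times = {t for sid, t in flagged if sid == curve.subject_id}
    if not bad_times:
        return curve
    keep = np.array([t not in bad_times for t in curve.times])
    return PlasmaCurve(
        subject_id=curve.subject_id,
        times=curve.times[keep],
        concentrations=curve.concentrations[keep],
        kind=curve.kind,
        decay_corrected=curve.decay_corrected,
    )


def summarize_cohort(results: list[NCAResult]) -> CohortSummary:
    """Min/max/median/mean/sample-SD per parameter across subjects.

    A single-subject cohort reports SD 0 and sets ``single_subject``.
    """
    if not results:
        raise ValueError("need at least one NCA result")
    df = pd.DataFrame([r.as_dict() for r in results])
    single = len(results) == 1
    rows = {}
    for p in NCA_PARAMETERS:
        v = df[p].to_numpy(dtype=float)
        rows[p] = {
            "min": v.min(),
            "max": v.max(),
            "median": float(np.median(v)),
            "mean": v.mean(),
            "stdev": 0.0 if single else float(v.std(ddof=1)),
        }
    table = pd.DataFrame(rows).T[["min", "max", "median", "mean", "stdev"]]
    return CohortSummary(table=table, n_subjects=len(results), single_subject=single)
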