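"""Piecewise sums of (polynomial x exponential) terms.

The plasma concentration of a linear compartment model is, on each time
segment (during and after a zero-order infusion), a finite sum of terms
``amp * tau**power * exp(-rate * tau)`` with ``tau`` the time since the
segment start and ``power`` in {0, 1}.  This module evaluates, integrates
and convolves such piecewise representations in closed form, which makes
the organ-exchange kinetics exact rather than numerically integrated.

Only first-order convolution against a positive-rate kernel is ever
needed (plasma -> interstitium), so powers never exceed 1 except in the
exact-resonance case rate == kernel rate, which produces a power-1 term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Term", "Segment", "PiecewiseExp", "curve_to_piecewise"]

_RES_TOL = 1e-12  # relative rate gap below which convolution uses the resonant form


@dataclass(frozen=True)
class Term:
    """One term amp * tau**power * exp(-rate * tau); power is 0 or 1."""

    amp: float
    rate: float
    power: int = 0


def _term_value(term: Term, tau: np.ndarray) -> np.ndarray:
    v = term.amp * np.exp(-term.rate * tau)
    if term.power:
        v = v * tau
    return v


def _term_integral(term: Term, tau: np.ndarray) -> np.ndarray:
    """Integral of the term from 0 to tau (tau >= 0)."""
    a, r = term.amp, term.rate
    if term.power == 0:
        if r == 0.0:
            return a * tau
        return a * (-np.expm1(-r * tau)) / r
    if r == 0.0:
        return a * tau**2 / 2.0
    x = r * tau
    return a * (1.0 - np.exp(-x) * (1.0 + x)) / r**2


@dataclass(frozen=True)
class Segment:
    """Terms valid on [t0, t1); tau = t - t0."""

    t0: float
    t1: float
    terms: tuple[Term, ...]

    def value(self, tau: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(tau, dtype=float))
        for term in self.terms:
            out += _term_value(term, tau)
        return out

    def integral(self, tau: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(tau, dtype=float))
        for term in self.terms:
            out += _term_integral(term, tau)
        return out


class PiecewiseExp:
    """A function of time represented as contiguous exponential-sum segments.

    Segments must be contiguous and start at a common origin; the last
    segment may extend to infinity.
    """

    def __init__(self, segments: list[Segment]):
        if not segments:
            raise ValueError("need at least one segment")
        for a, b in zip(segments, segments[1:]):
            if not math.isclose(a.t1, b.t0, rel_tol=0, abs_tol=1e-9):
                raise ValueError("segments must be contiguous")
        self.segments = segments
        self.t_start = segments[0].t0
        # cumulative integral at each segment start
        cum = [0.0]
        for seg in segments[:-1]:
            cum.append(cum[-1] + float(seg.integral(np.asarray(seg.t1 - seg.t0))))
        self._cum = np.asarray(cum)
        self._starts = np.asarray([s.t0 for s in segments])

    def _locate(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._starts, t, side="right") - 1
        return np.clip(idx, 0, len(self.segments) - 1)

    def value(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = self._locate(t)
        out = np.empty_like(t)
        for i in np.unique(idx):
            sel = idx == i
            out[sel] = self.segments[i].value(t[sel] - self.segments[i].t0)
        return out

    def integral(self, t) -> np.ndarray:
        """Integral from the start of the first segment to t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = self._locate(t)
        out = np.empty_like(t)
        for i in np.unique(idx):
            sel = idx == i
            out[sel] = self._cum[i] + self.segments[i].integral(
                t[sel] - self.segments[i].t0
            )
        return out

    def convolve(self, kernel_rate: float, gain: float, y0: float = 0.0) -> "PiecewiseExp":
        """Closed-form solution y of y' = gain * f(t) - kernel_rate * y, y(t_start) = y0.

        ``f`` is this piecewise function.  Requires kernel_rate > 0.
        """
        if kernel_rate <= 0:
            raise ValueError("kernel_rate must be positive")
        out_segments: list[Segment] = []
        carry = y0
        for seg in self.segments:
            terms = [Term(carry, kernel_rate, 0)]
            for term in seg.terms:
                terms.extend(_convolve_term(term, kernel_rate, gain))
            new_seg = Segment(seg.t0, seg.t1, tuple(terms))
            out_segments.append(new_seg)
            if math.isfinite(seg.t1):
                carry = float(new_seg.value(np.asarray(seg.t1 - seg.t0)))
        return PiecewiseExp(out_segments)


def _convolve_term(term: Term, kappa: float, gain: float) -> list[Term]:
    """gain * integral_0^tau exp(-kappa (tau - s)) * term(s) ds, as Terms."""
    a, r = gain * term.amp, term.rate
    delta = kappa - r
    if term.power == 0:
        if abs(delta) <= _RES_TOL * max(abs(kappa), abs(r)):
            return [Term(a, kappa, 1)]
        return [Term(a / delta, r, 0), Term(-a / delta, kappa, 0)]
    # power == 1 (arises only from linear ramps, rate 0, so delta != 0 there)
    if abs(delta) <= _RES_TOL * max(abs(kappa), abs(r)):
        raise NotImplementedError("resonant convolution of a power-1 term")
    return [
        Term(a / delta, r, 1),
        Term(-a / delta**2, r, 0),
        Term(a / delta**2, kappa, 0),
    ]


def curve_to_piecewise(times, values, extend: bool = True) -> PiecewiseExp:
    """Piecewise-exponential interpolant of sampled positive data.

    Between consecutive samples the curve is log-linear (a single
    exponential), the standard interpolation for concentration declines;
    where a sample is zero the segment falls back to linear.  With
    ``extend`` the last segment is continued to infinity at the terminal
    rate (or held constant when the last two samples are equal or either
    is zero).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")

    segments: list[Segment] = []
    last_terms: tuple[Term, ...] = (Term(c[-1], 0.0, 0),)
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c0 > 0 and c1 > 0:
            rate = math.log(c0 / c1) / dt
            if abs(rate) < 1e-14:
                rate = 0.0
            terms: tuple[Term, ...] = (Term(c0, rate, 0),)
            if i == t.size - 2 and rate > 0:
                last_terms = (Term(c1, rate, 0),)
        else:  # linear ramp through a zero
            slope = (c1 - c0) / dt
            terms = (Term(c0, 0.0, 0), Term(slope, 0.0, 1))
        segments.append(Segment(float(t[i]), float(t[i + 1]), terms))
    if extend:
        segments.append(Segment(float(t[-1]), math.inf, last_terms))
    return PiecewiseExp(segments)
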