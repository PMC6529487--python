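"""Two-compartment plasma kinetics with zero-order infusion, in closed form.

Amounts in the central (plasma, volume V1) and peripheral (tissue,
volume V2) compartments follow

    dA1/dt = in(t) - (CL/V1) A1 - (Q/V1) A1 + (Q/V2) A2
    dA2/dt =                     (Q/V1) A1 - (Q/V2) A2

with clearance CL, distributional clearance Q, and a zero-order infusion
``in(t) = dose/TI`` for ``t in [0, TI]`` (bolus when TI = 0).  The
solution is biexponential: the fast eigenvalue shapes the distribution
(alpha) phase, the slow eigenvalue the terminal (beta) elimination phase.
The model is solved by eigendecomposition of the 2x2 rate matrix, giving
exact concentrations, integrals and a piecewise-exponential
representation used by the organ extravasation kinetics.
"""

from __future__ import annotations

import math

import numpy as np

from ._expsum import PiecewiseExp, Segment, Term
from .config import ConfigError, SimulationConfig
from .types import PlasmaCurve

__all__ = ["TwoCompartmentModel", "simulate_plasma"]


class TwoCompartmentModel:
    """Closed-form two-compartment IV model (amounts in ng, volumes in mL)."""

    def __init__(
        self,
        dose: float,
        central_volume: float,
        clearance: float,
        intercompartment_clearance: float = 0.0,
        peripheral_volume: float = 1.0,
        infusion_duration: float = 0.0,
    ):
        if dose <= 0 or central_volume <= 0 or clearance <= 0 or peripheral_volume <= 0:
            raise ConfigError("dose, volumes and clearance must be positive")
        if intercompartment_clearance < 0 or infusion_duration < 0:
            raise ConfigError("Q and infusion duration must be non-negative")
        self.dose = float(dose)
        self.v1 = float(central_volume)
        self.v2 = float(peripheral_volume)
        self.cl = float(clearance)
        self.q = float(intercompartment_clearance)
        self.ti = float(infusion_duration)

        k10 = self.cl / self.v1
        k12 = self.q / self.v1
        k21 = self.q / self.v2
        self.K = np.array([[-(k10 + k12), k21], [k12, -k21]])
        evals, evecs = np.linalg.eig(self.K)
        order = np.argsort(evals)  # most negative (fast) first
        evals, evecs = evals[order], evecs[:, order]
        self._lams = -evals  # decay rates, fast then slow; slow may be 0 when Q=0
        if abs(self._lams[0] - self._lams[1]) <= 1e-12 * max(abs(self._lams[0]), 1e-30):
            raise ConfigError(
                "degenerate eigenvalues; perturb Q or the volumes slightly"
            )
        self._P = evecs
        self._Pinv = np.linalg.inv(evecs)
        self._central = self._build_piecewise(component=0)
        self._peripheral = self._build_piecewise(component=1)

    # -- construction -------------------------------------------------

    def _free_terms(self, state: np.ndarray, component: int, t0: float) -> Segment:
        """Free decay from amounts ``state`` at t0, as amounts of one compartment."""
        coeffs = self._Pinv @ state
        terms = tuple(
            Term(float(self._P[component, i] * coeffs[i]), float(self._lams[i]), 0)
            for i in range(2)
        )
        return Segment(t0, math.inf, terms)

    def _forced_terms(self, rate: float, component: int) -> tuple[Term, ...]:
        """Response amounts to constant input u = [rate, 0] from rest at t = 0."""
        z = self._Pinv @ np.array([rate, 0.0])
        terms: list[Term] = []
        for i, lam in enumerate(self._lams):
            amp = float(self._P[component, i] * z[i])
            if amp == 0.0:
                continue
            if abs(lam) < 1e-300:
                terms.append(Term(amp, 0.0, 1))  # pure ramp: amp * t
            else:
                # amp * (1 - exp(-lam t)) / lam
                terms.append(Term(amp / lam, 0.0, 0))
                terms.append(Term(-amp / lam, float(lam), 0))
        return tuple(terms)

    def _build_piecewise(self, component: int) -> PiecewiseExp:
        volume = self.v1 if component == 0 else self.v2

        def scale(seg: Segment) -> Segment:
            return Segment(
                seg.t0, seg.t1, tuple(Term(t.amp / volume, t.rate, t.power) for t in seg.terms)
            )

        if self.ti == 0.0:
            seg = self._free_terms(np.array([self.dose, 0.0]), component, 0.0)
            return PiecewiseExp([scale(seg)])
        rate = self.dose / self.ti
        inf_seg = Segment(0.0, self.ti, self._forced_terms(rate, component))
        a_ti = np.array(
            [
                float(Segment(0.0, self.ti, self._forced_terms(rate, comp)).value(np.asarray(self.ti)))
                for comp in (0, 1)
            ]
        )
        post_seg = self._free_terms(a_ti, component, self.ti)
        return PiecewiseExp([scale(inf_seg), scale(post_seg)])

    # -- public surface ------------------------------------------------

    @classmethod
    def from_nca_parameters(
        cls,
        dose: float,
        clearance: float,
        vss: float,
        t_half_fast: float,
        t_half_terminal: float,
        infusion_duration: float = 0.0,
    ) -> "TwoCompartmentModel":
        """Build the model from NCA-level parameters.

        Given clearance, steady-state volume Vss = V1 + V2 and the two
        phase half-lives, the micro-constants follow from the standard
        eigenvalue relations lam1*lam2 = k10*k21 and
        lam1+lam2 = k10 + k12 + k21 with Vss = V1 (1 + k12/k21).
        """
        lam1 = math.log(2.0) / t_half_fast
        lam2 = math.log(2.0) / t_half_terminal
        if lam1 <= lam2:
            raise ConfigError("fast half-life must be shorter than terminal half-life")
        denom = lam1 + lam2 - lam1 * lam2 * vss / clearance
        if denom <= 0:
            raise ConfigError("inconsistent NCA parameters (no positive V1)")
        v1 = clearance / denom
        if vss <= v1:
            raise ConfigError("Vss must exceed the central volume implied by CL")
        k21 = lam1 * lam2 * v1 / clearance
        v2 = vss - v1
        q = k21 * v2
        return cls(dose, v1, clearance, q, v2, infusion_duration)

    @property
    def eigenvalues(self) -> tuple[float, float]:
        """(fast, slow) decay rates of the biexponential, 1/h."""
        return float(self._lams[0]), float(self._lams[1])

    @property
    def terminal_half_life(self) -> float:
        lam_slow = self._lams[1]
        if lam_slow <= 0:
            return math.inf
        return math.log(2.0) / float(lam_slow)

    @property
    def vss(self) -> float:
        return self.v1 + self.v2

    def concentration(self, t) -> np.ndarray:
        """Central (plasma) concentration, ng/mL, for t >= 0."""
        return self._central.value(t)

    def amounts(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Amounts (ng) in central and peripheral compartments."""
        return self._central.value(t) * self.v1, self._peripheral.value(t) * self.v2

    def eliminated(self, t) -> np.ndarray:
        """Cumulative amount cleared from plasma: CL * integral of C."""
        return self.cl * self._central.integral(t)

    def infused(self, t) -> np.ndarray:
        """Cumulative amount administered by time t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.ti == 0.0:
            return np.full_like(t, self.dose)
        return self.dose * np.clip(t / self.ti, 0.0, 1.0)

    def mass_balance_residual(self, t) -> np.ndarray:
        """(central + peripheral + eliminated - infused) / dose; ~0 always."""
        a1, a2 = self.amounts(t)
        return (a1 + a2 + self.eliminated(t) - self.infused(t)) / self.dose

    def piecewise(self) -> PiecewiseExp:
        """Plasma concentration as a piecewise exponential (for convolution)."""
        return self._central

    def auc_to(self, t) -> np.ndarray:
        """Integral of plasma concentration from 0 to t (ng*h/mL)."""
        return self._central.integral(t)


def model_from_config(config: SimulationConfig) -> TwoCompartmentModel:
    return TwoCompartmentModel(
        dose=config.dose_mass,
        central_volume=config.central_volume,
        clearance=config.clearance,
        intercompartment_clearance=config.intercompartment_clearance,
        peripheral_volume=config.peripheral_volume,
        infusion_duration=config.infusion_duration,
    )


def simulate_plasma(
    config: SimulationConfig,
    subject_id: str = "sim",
    kind: str = "total",
    times=None,
    include_predose: bool = True,
) -> PlasmaCurve:
    """Noise-free plasma concentration-time curve for one subject.

    ``kind="total"`` yields protein mass concentration (ng/mL);
    ``kind="radio"`` scales by the dose specific activity to
    decay-corrected radioactivity (Bq/mL).  Times default to the blood
    sampling schedule merged with the scan times (blood draws accompany
    every PET scan); a pre-dose zero sample is prepended when the model
    has an infusion phase.
    """
    model = model_from_config(config)
    if times is None:
        times = np.asarray(config.sample_times, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    conc = model.concentration(times)
    if include_predose and config.infusion_duration > 0 and times[0] > 0:
        times = np.concatenate([[0.0], times])
        conc = np.concatenate([[0.0], conc])
    if kind == "radio":
        conc = conc * config.specific_activity
    return PlasmaCurve(
        subject_id=subject_id,
        times=times,
        concentrations=np.maximum(conc, 0.0),
        kind=kind,
        decay_corrected=True,
    )
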