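"""Physical decay and measurement noise applied to noise-free truth.

The simulator works in decay-corrected truth; a measurement is obtained
by applying 89Zr physical decay, ``2**(-t/T_half)``, and multiplicative
lognormal noise with unit mean and a given coefficient of variation
(counting/PET noise is positive and roughly proportional to the signal).
With ``noise_cv = 0`` the measured series is exactly the decayed truth,
so decay-correcting it recovers the truth bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigError, SimulationConfig
from .types import PlasmaCurve

__all__ = ["decay_factor", "apply_decay_and_noise", "measure_curve"]


def decay_factor(t, half_life: float):
    """Fraction of activity remaining after time t: 2**(-t/half_life)."""
    if half_life <= 0:
        raise ConfigError("half-life must be positive")
    return np.power(2.0, -np.asarray(t, dtype=float) / half_life)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=n))


def apply_decay_and_noise(
    values,
    times,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """measured = truth * 2**(-t/T_half) * lognormal(mean 1, cv).

    Deterministic given the generator (or ``config.seed`` when ``rng``
    is omitted).
    """
    if config.noise_cv < 0:
        raise ConfigError("noise_cv must be non-negative")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    measured = values * decay_factor(times, config.isotope_half_life)
    return measured * _lognormal_factors(rng, config.noise_cv, values.size).reshape(values.shape)


def measure_curve(
    curve: PlasmaCurve,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    decay_corrected: bool = True,
) -> PlasmaCurve:
    """Noisy measurement of a plasma curve.

    Gamma counters report decay-corrected values, so by default only the
    noise is applied; with ``decay_corrected=False`` the raw decaying
    measurement is returned instead.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noisy = curve.concentrations * _lognormal_factors(
        rng, config.noise_cv, curve.concentrations.size
    )
    if not decay_corrected:
        noisy = noisy * decay_factor(curve.times, config.isotope_half_life)
    return PlasmaCurve(
        subject_id=curve.subject_id,
        times=curve.times,
        concentrations=noisy,
        kind=curve.kind,
        decay_corrected=decay_corrected,
    )
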