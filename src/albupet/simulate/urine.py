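"""Urinary excretion of radioactivity.

Renal loss of the tracer (albumin-bound protein passing the glomerular
barrier plus any early free label) is modelled as a rate proportional to
the plasma concentration, scaled so that the cumulative decay-corrected
excretion at 24 h equals the configured fraction of the administered
activity (~4 % in the study this package models).  Urine concentration
over a collection interval follows from a constant urine flow.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .organs import _plasma_piecewise
from .plasma import model_from_config
from .types import UrineSeries

__all__ = ["simulate_urine"]

_DEFAULT_TIMES = tuple(float(t) for t in np.arange(0.0, 170.0, 2.0))


def simulate_urine(
    config: SimulationConfig,
    plasma=None,
    subject_id: str = "sim",
    times=None,
) -> UrineSeries:
    """Noise-free cumulative urine activity (Bq, decay-corrected).

    ``plasma`` may be a TwoCompartmentModel, a PlasmaCurve or None (the
    plasma model implied by ``config``).  The series is monotone
    non-decreasing and reaches ``urine_fraction_24h * dose_activity``
    exactly at t = 24 h.
    """
    if plasma is None:
        plasma = model_from_config(config)
    pw = _plasma_piecewise(plasma)
    if times is None:
        times = np.asarray(_DEFAULT_TIMES, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    exposure = pw.integral(times)
    exposure_24 = float(pw.integral(24.0)[0])
    if exposure_24 <= 0:
        cumulative = np.zeros_like(exposure)
    else:
        cumulative = (
            config.urine_fraction_24h * config.dose_activity * exposure / exposure_24
        )
    return UrineSeries(
        subject_id=subject_id,
        times=times,
        cumulative=cumulative,
        dose_activity=config.dose_activity,
    )
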