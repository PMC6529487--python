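"""Organ time-activity simulation: vascular, interstitial and residualized pools.

An organ's decay-corrected activity concentration (per mL of whole
organ) is the sum of three contributions:

* vascular: ``tp_min * C_p(t)`` — tracer in the organ plasma volume;
* interstitial: ``(V_I/V_org) * C_I(t)`` where the interstitial
  concentration relaxes toward its equilibrium with plasma,

      dC_I/dt = k_exchange * (equilibrium_ratio * C_p - C_I);

* residualized: label trapped after catabolism of extravasated protein,

      dR/dt = k_residualize * (V_I/V_org) * C_I,

  which is non-decreasing in decay-corrected terms (residualizing
  radiometal chemistry).

With constant plasma and equilibrium_ratio = 1 the tissue-to-plasma
ratio tends to ``tp_max``; with k_exchange = 0 it stays at ``tp_min``
(vascular confinement, the brain case).  All pools are evaluated in
closed form from the piecewise-exponential plasma representation.
"""

from __future__ import annotations

import numpy as np

from ..physiology import OrganPhysiology, tp_min
from ._expsum import PiecewiseExp, curve_to_piecewise
from .config import SimulationConfig
from .plasma import TwoCompartmentModel
from .types import OrganTimeActivity, PlasmaCurve

__all__ = ["simulate_organ"]


class UnknownOrganError(KeyError):
    """Raised when an organ has no kinetic parameters in the config."""


def _plasma_piecewise(plasma) -> PiecewiseExp:
    if isinstance(plasma, TwoCompartmentModel):
        return plasma.piecewise()
    if isinstance(plasma, PlasmaCurve):
        return curve_to_piecewise(plasma.times, plasma.concentrations)
    if isinstance(plasma, PiecewiseExp):
        return plasma
    raise TypeError(f"unsupported plasma input: {type(plasma).__name__}")


def simulate_organ(
    config: SimulationConfig,
    organ: OrganPhysiology,
    plasma,
    times=None,
) -> OrganTimeActivity:
    """Noise-free organ time-activity curve driven by a plasma time course.

    Parameters
    ----------
    config : SimulationConfig
        Supplies the organ's kinetic parameters (``config.organ_params``).
    organ : OrganPhysiology
        Volume bookkeeping for the vascular/interstitial split.
    plasma : TwoCompartmentModel | PlasmaCurve | PiecewiseExp
        The driving plasma concentration.  A sampled curve is
        interpolated log-linearly between its samples.
    times : array-like of h, optional
        Evaluation times (default: the configured scan times).

    Returns
    -------
    OrganTimeActivity with the three pools in the plasma input's units.
    """
    try:
        kin = config.organ_params[organ.organ_name]
    except KeyError:
        raise UnknownOrganError(
            f"no kinetic parameters configured for organ {organ.organ_name!r}"
        ) from None
    if times is None:
        times = np.asarray(config.scan_times, dtype=float)
    else:
        times = np.asarray(times, dtype=float)

    pw = _plasma_piecewise(plasma)
    cp = pw.value(times)
    f_i = organ.interstitial_fraction

    vascular = tp_min(organ) * cp
    if kin.k_exchange > 0:
        ci_pw = pw.convolve(
            kernel_rate=kin.k_exchange,
            gain=kin.k_exchange * kin.equilibrium_ratio,
        )
        interstitial = f_i * ci_pw.value(times)
        residualized = kin.k_residualize * f_i * ci_pw.integral(times)
    else:
        interstitial = np.zeros_like(cp)
        residualized = np.zeros_like(cp)

    return OrganTimeActivity(
        organ_name=organ.organ_name,
        times=times,
        vascular=np.maximum(vascular, 0.0),
        interstitial=np.maximum(interstitial, 0.0),
        residualized=np.maximum(residualized, 0.0),
        plasma_conc=cp,
        blood_fraction=kin.blood_fraction,
    )
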