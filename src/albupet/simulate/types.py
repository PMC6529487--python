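"""Core data containers produced by the simulator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PlasmaCurve", "OrganTimeActivity", "UrineSeries", "VoxelPhantom"]


@dataclass
class PlasmaCurve:
    """Subject-level plasma concentration-time series.

    ``kind`` distinguishes gamma-counted radioactivity ("radio", Bq/mL)
    from total-protein mass-spectrometry concentrations ("total", ng/mL).
    Times are hours from the start of infusion.
    """

    subject_id: str
    times: np.ndarray
    concentrations: np.ndarray
    kind: str = "total"
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValueError("times and concentrations must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.kind not in ("radio", "total"):
            raise ValueError(f"kind must be 'radio' or 'total', got {self.kind!r}")

    def to_frame(self) -> pd.DataFrame:
        unit = "Bq/mL" if self.kind == "radio" else "ng/mL"
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "time_h": self.times,
                "value": self.concentrations,
                "unit": unit,
                "kind": self.kind,
                "decay_corrected": self.decay_corrected,
            }
        )


@dataclass
class OrganTimeActivity:
    """Per-organ decay-corrected concentration time course, by compartment.

    ``vascular``, ``interstitial`` and ``residualized`` are organ-level
    concentrations (activity per mL of whole organ), in the same units as
    the plasma curve that drove the simulation.  ``plasma_conc`` carries
    the driving plasma concentration at the same times so that
    blood-pool contamination of a measurement volume (e.g. heart chambers
    inside the VoI) can be reconstructed via :meth:`voi_conc`.
    """

    organ_name: str
    times: np.ndarray
    vascular: np.ndarray
    interstitial: np.ndarray
    residualized: np.ndarray
    plasma_conc: np.ndarray
    blood_fraction: float = 0.0

    def __post_init__(self) -> None:
        arrays = [self.times, self.vascular, self.interstitial, self.residualized, self.plasma_conc]
        arrays = [np.asarray(a, dtype=float) for a in arrays]
        (self.times, self.vascular, self.interstitial, self.residualized, self.plasma_conc) = arrays
        n = self.times.shape
        for a in arrays[1:]:
            if a.shape != n:
                raise ValueError("all component arrays must match times in shape")
        for name in ("vascular", "interstitial", "residualized"):
            if np.any(getattr(self, name) < -1e-12):
                raise ValueError(f"{name} concentrations must be non-negative")
        if not 0 <= self.blood_fraction < 1:
            raise ValueError("blood_fraction must lie in [0, 1)")

    @property
    def conc(self) -> np.ndarray:
        """Total organ concentration: vascular + interstitial + residualized."""
        return self.vascular + self.interstitial + self.residualized

    def voi_conc(self) -> np.ndarray:
        """Concentration a measurement volume sees, mixing in chamber blood."""
        return (1.0 - self.blood_fraction) * self.conc + self.blood_fraction * self.plasma_conc

    def tp(self) -> np.ndarray:
        """Tissue-to-plasma ratio time course of the measurement volume."""
        return self.voi_conc() / self.plasma_conc


@dataclass
class UrineSeries:
    """Cumulative urinary excretion of radioactivity.

    ``cumulative`` is the decay-corrected activity (Bq) excreted by each
    time; urine concentration over an interval follows from a constant
    urine production rate.
    """

    subject_id: str
    times: np.ndarray
    cumulative: np.ndarray
    dose_activity: float
    urine_flow_mL_h: float = 62.5  # ~1.5 L/day

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.cumulative) < -1e-9 * max(1.0, self.dose_activity)):
            raise ValueError("cumulative excretion must be non-decreasing")

    def interval_concentration(self, t0: float, t1: float) -> float:
        """Mean urine concentration (Bq/mL) over the collection [t0, t1]."""
        c0, c1 = np.interp([t0, t1], self.times, self.cumulative)
        return float((c1 - c0) / (self.urine_flow_mL_h * (t1 - t0)))


@dataclass
class VoxelPhantom:
    """A labelled 3-D activity volume standing in for one PET/CT acquisition.

    ``activity_map`` holds as-measured (physically decaying) activity
    concentration in Bq/mL; ``label_map`` holds integer organ labels with
    0 = outside the body, and ``label_names`` maps organ names (including
    the mandatory "body" background) to labels.
    """

    voxel_spacing: tuple[float, float, float]  # mm
    activity_map: np.ndarray
    label_map: np.ndarray
    label_names: dict[str, int]
    body_weight: float  # g
    injected_activity: float  # Bq
    t_scan: float  # h

    def __post_init__(self) -> None:
        self.activity_map = np.asarray(self.activity_map, dtype=float)
        self.label_map = np.asarray(self.label_map)
        if self.activity_map.shape != self.label_map.shape:
            raise ValueError("activity and label maps must have the same shape")
        if np.any(self.activity_map < 0):
            raise ValueError("activity map must be non-negative everywhere")
        if "body" not in self.label_names:
            raise ValueError("phantom must include a 'body' background label")
        present = set(np.unique(self.label_map).tolist())
        for name, lbl in self.label_names.items():
            if lbl not in present:
                raise ValueError(f"label {name!r} ({lbl}) has no voxels")
        if self.body_weight <= 0 or self.injected_activity <= 0:
            raise ValueError("body weight and injected activity must be positive")

    @property
    def voxel_volume_mL(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz / 1000.0
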