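"""Digital voxel phantom: ellipsoidal organs in a labelled 3-D grid.

The phantom stands in for a whole-body PET/CT acquisition: each organ is
a non-overlapping ellipsoid carrying its simulated activity
concentration, embedded in a body ellipsoid carrying a background
(blood-pool/soft-tissue) value, on a regular grid with known voxel
spacing.  The stored activity map is *as measured* (physically
decaying); quantification decay-corrects back to administration time.
Phantoms round-trip through a NIfTI volume pair plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import SimulationConfig
from .noise import decay_factor
from .types import VoxelPhantom

__all__ = [
    "Ellipsoid",
    "PhantomGeometry",
    "GeometryError",
    "default_geometry",
    "build_phantom",
    "save_phantom",
    "load_phantom",
]


class GeometryError(ValueError):
    """Raised for overlapping or out-of-grid organ ellipsoids."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes, both in mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    @property
    def volume_mL(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def mask(self, shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> np.ndarray:
        """Boolean mask of voxels whose centers lie inside the ellipsoid."""
        grids = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
        r2 = sum(
            (((g + 0.5) * s - c) / ax) ** 2
            for g, s, c, ax in zip(grids, spacing, self.center, self.semi_axes)
        )
        return r2 <= 1.0


@dataclass(frozen=True)
class PhantomGeometry:
    """Grid plus the body and per-organ ellipsoids."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm per voxel along each axis
    body: Ellipsoid
    organs: dict[str, Ellipsoid]


def default_geometry(organs=None) -> PhantomGeometry:
    """A compact head-to-thigh layout on a 60x40x40 grid at 6 mm spacing.

    Coordinates are (axial, coronal, sagittal) mm; organs are placed with
    clearance so no two ellipsoids share a voxel.  Restrict to a subset
    of organs by passing their names.
    """
    all_organs = {
        "brain": Ellipsoid((40.0, 120.0, 120.0), (30.0, 28.0, 28.0)),
        "parotid_gland": Ellipsoid((50.0, 120.0, 75.0), (13.0, 13.0, 13.0)),
        "lung": Ellipsoid((95.0, 120.0, 70.0), (33.0, 24.0, 24.0)),
        "heart": Ellipsoid((100.0, 120.0, 130.0), (22.0, 20.0, 20.0)),
        "liver": Ellipsoid((160.0, 120.0, 80.0), (33.0, 29.0, 29.0)),
        "spleen": Ellipsoid((160.0, 120.0, 170.0), (20.0, 15.0, 15.0)),
        "kidney": Ellipsoid((220.0, 120.0, 80.0), (22.0, 15.0, 15.0)),
        "pancreas": Ellipsoid((207.0, 120.0, 150.0), (14.0, 12.0, 20.0)),
        "testis": Ellipsoid((255.0, 117.0, 117.0), (16.0, 16.0, 16.0)),
        "muscle": Ellipsoid((300.0, 120.0, 80.0), (38.0, 24.0, 24.0)),
        "bone_marrow": Ellipsoid((300.0, 120.0, 170.0), (34.0, 12.0, 12.0)),
    }
    if organs is not None:
        unknown = set(organs) - set(all_organs)
        if unknown:
            raise GeometryError(f"no default placement for organs: {sorted(unknown)}")
        all_organs = {k: v for k, v in all_organs.items() if k in organs}
    return PhantomGeometry(
        shape=(60, 40, 40),
        spacing=(6.0, 6.0, 6.0),
        body=Ellipsoid((180.0, 120.0, 120.0), (178.0, 118.0, 118.0)),
        organs=all_organs,
    )


def build_phantom(
    config: SimulationConfig,
    organ_concs: dict[str, float],
    t_scan: float,
    geometry: PhantomGeometry | None = None,
    background_conc: float = 0.0,
    decay_corrected_input: bool = True,
) -> VoxelPhantom:
    """Voxelize per-organ activity concentrations at one scan time.

    Parameters
    ----------
    organ_concs : dict organ -> Bq/mL
        The concentration each organ VoI should carry (decay-corrected
        truth by default; physical decay at ``t_scan`` is then applied
        to produce the as-measured map).
    background_conc : Bq/mL
        Value for body voxels outside any organ (decay-corrected scale
        as above).

    Raises
    ------
    GeometryError if any two organ ellipsoids overlap or an organ lies
    outside the body ellipsoid.
    """
    if geometry is None:
        geometry = default_geometry(organs=list(organ_concs))
    missing = set(organ_concs) - set(geometry.organs)
    if missing:
        raise GeometryError(f"geometry lacks placements for: {sorted(missing)}")

    decay = decay_factor(t_scan, config.isotope_half_life) if decay_corrected_input else 1.0
    body_mask = geometry.body.mask(geometry.shape, geometry.spacing)
    labels = np.zeros(geometry.shape, dtype=np.uint16)
    activity = np.zeros(geometry.shape, dtype=float)
    labels[body_mask] = 1
    activity[body_mask] = background_conc * decay
    label_names = {"body": 1}

    claimed = np.zeros(geometry.shape, dtype=bool)
    for idx, (name, conc) in enumerate(sorted(organ_concs.items()), start=2):
        ell = geometry.organs[name]
        mask = ell.mask(geometry.shape, geometry.spacing)
        if not mask.any():
            raise GeometryError(f"organ {name!r} has no voxels on this grid")
        if (mask & ~body_mask).any():
            raise GeometryError(f"organ {name!r} extends outside the body")
        if (mask & claimed).any():
            raise GeometryError(f"organ {name!r} overlaps another organ")
        claimed |= mask
        labels[mask] = idx
        activity[mask] = conc * decay
        label_names[name] = idx

    return VoxelPhantom(
        voxel_spacing=geometry.spacing,
        activity_map=activity,
        label_map=labels,
        label_names=label_names,
        body_weight=config.body_weight,
        injected_activity=config.dose_activity,
        t_scan=float(t_scan),
    )


def save_phantom(phantom: VoxelPhantom, directory: str | Path, stem: str = "phantom") -> None:
    """Write activity (float32) and label (uint16) NIfTI volumes + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.voxel_spacing) + [1.0])
    nib.save(
        nib.Nifti1Image(phantom.activity_map.astype(np.float32), affine),
        directory / f"{stem}_activity.nii",
    )
    nib.save(
        nib.Nifti1Image(phantom.label_map.astype(np.uint16), affine),
        directory / f"{stem}_labels.nii",
    )
    sidecar = {
        "voxel_spacing_mm": list(phantom.voxel_spacing),
        "label_names": phantom.label_names,
        "body_weight_g": phantom.body_weight,
        "injected_activity_Bq": phantom.injected_activity,
        "t_scan_h": phantom.t_scan,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_phantom(directory: str | Path, stem: str = "phantom") -> VoxelPhantom:
    """Inverse of :func:`save_phantom`."""
    directory = Path(directory)
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    activity = np.asanyarray(nib.load(directory / f"{stem}_activity.nii").dataobj, dtype=float)
    labels = np.asanyarray(nib.load(directory / f"{stem}_labels.nii").dataobj)
    return VoxelPhantom(
        voxel_spacing=tuple(sidecar["voxel_spacing_mm"]),
        activity_map=activity,
        label_map=labels.astype(np.uint16),
        label_names={k: int(v) for k, v in sidecar["label_names"].items()},
        body_weight=sidecar["body_weight_g"],
        injected_activity=sidecar["injected_activity_Bq"],
        t_scan=sidecar["t_scan_h"],
    )
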