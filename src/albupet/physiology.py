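"""Organ volume bookkeeping and theoretical tissue-to-plasma ratio bounds.

For a tracer that cannot cross cell membranes, the organ-level activity
concentration is bracketed by two static limits derived from the organ's
vascular and interstitial volumes:

* the *minimum* tissue-to-plasma ratio, reached when the tracer is confined
  to the organ vasculature::

      (t/p)_min = V_P / V_org

* the *maximum* ratio, reached when the interstitial concentration has
  equilibrated with plasma::

      (t/p)_max = (V_P + V_I) / V_org

where ``V_P`` is the organ plasma volume, ``V_I`` the interstitial volume
and ``V_org`` the total organ volume (all in mL).  Both ratios are
dimensionless and scale-invariant in the volumes.

A table of per-organ volumes for a reference adult male is bundled with the
package (``albupet/data/organ_volumes.csv``); :func:`load_physiology_table`
reads it, or any user-supplied CSV with the same columns.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "OrganPhysiology",
    "TPBounds",
    "InvalidPhysiologyError",
    "tp_min",
    "tp_max",
    "tp_bounds",
    "load_physiology_table",
    "write_physiology_table",
]

#: Organs guaranteed to be present in the bundled default table.
DEFAULT_ORGANS = (
    "brain",
    "lung",
    "liver",
    "spleen",
    "kidney",
    "heart",
    "muscle",
    "pancreas",
    "testis",
    "bone_marrow",
    "parotid_gland",
)

_COLUMNS = ["organ", "V_org_mL", "V_P_mL", "V_I_mL", "mass_fraction"]


class InvalidPhysiologyError(ValueError):
    """Raised when organ volumes violate their physical constraints."""


@dataclass(frozen=True)
class OrganPhysiology:
    """Static volume parameters of one organ.

    Parameters
    ----------
    organ_name : str
        Organ identifier; unique within a table.
    V_org : float
        Total organ volume, mL.  Must be > 0.
    V_P_org : float
        Organ plasma (vascular) volume, mL.
    V_I_org : float
        Organ interstitial volume, mL.
    mass_fraction : float
        Organ mass / body mass, in (0, 1).
    density : float
        Tissue density, g/mL (default 1.0; activity ratios are computed
        per mL so density only matters for mass bookkeeping).
    """

    organ_name: str
    V_org: float
    V_P_org: float
    V_I_org: float
    mass_fraction: float
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.V_org <= 0:
            raise InvalidPhysiologyError(
                f"{self.organ_name}: total volume must be positive, got {self.V_org}"
            )
        if self.V_P_org < 0 or self.V_I_org < 0:
            raise InvalidPhysiologyError(
                f"{self.organ_name}: plasma/interstitial volumes must be non-negative"
            )
        if self.V_P_org + self.V_I_org > self.V_org * (1 + 1e-12):
            raise InvalidPhysiologyError(
                f"{self.organ_name}: V_P + V_I = "
                f"{self.V_P_org + self.V_I_org} exceeds V_org = {self.V_org}"
            )
        if not 0 < self.mass_fraction < 1:
            raise InvalidPhysiologyError(
                f"{self.organ_name}: mass_fraction must lie in (0, 1), "
                f"got {self.mass_fraction}"
            )
        if self.density <= 0:
            raise InvalidPhysiologyError(f"{self.organ_name}: density must be positive")

    @property
    def interstitial_fraction(self) -> float:
        """V_I / V_org — the width of the [tp_min, tp_max] band."""
        return self.V_I_org / self.V_org


@dataclass(frozen=True)
class TPBounds:
    """Theoretical minimum and maximum tissue-to-plasma ratio of one organ."""

    organ_name: str
    tp_min: float
    tp_max: float

    def __post_init__(self) -> None:
        if not 0 <= self.tp_min <= self.tp_max <= 1 + 1e-12:
            raise InvalidPhysiologyError(
                f"{self.organ_name}: bounds ({self.tp_min}, {self.tp_max}) "
                "must satisfy 0 <= tp_min <= tp_max <= 1"
            )


def tp_min(phys: OrganPhysiology) -> float:
    """Lowest theoretical tissue-to-plasma ratio: tracer confined to vasculature."""
    return phys.V_P_org / phys.V_org


def tp_max(phys: OrganPhysiology) -> float:
    """Highest theoretical tissue-to-plasma ratio: interstitium equilibrated with plasma."""
    return (phys.V_P_org + phys.V_I_org) / phys.V_org


def tp_bounds(phys: OrganPhysiology) -> TPBounds:
    """Both bounds for one organ, as a :class:`TPBounds`."""
    return TPBounds(phys.organ_name, tp_min(phys), tp_max(phys))


def load_physiology_table(source: str | Path | None = None) -> dict[str, OrganPhysiology]:
    """Load a per-organ volume table and validate every row.

    Parameters
    ----------
    source : path-like, optional
        CSV with columns ``organ,V_org_mL,V_P_mL,V_I_mL,mass_fraction``
        (``#`` lines are comments).  When omitted, the bundled reference
        table is used.

    Returns
    -------
    dict mapping organ name to :class:`OrganPhysiology`.

    Raises
    ------
    InvalidPhysiologyError
        On a duplicate organ, a missing column, or a row that violates the
        volume invariants; the message names the offending row.
    """
    if source is None:
        with importlib.resources.files("albupet.data").joinpath(
            "organ_volumes.csv"
        ).open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(source, comment="#")

    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise InvalidPhysiologyError(f"physiology table missing columns: {missing}")
    dupes = df["organ"][df["organ"].duplicated()].tolist()
    if dupes:
        raise InvalidPhysiologyError(f"duplicate organ entries: {dupes}")

    table: dict[str, OrganPhysiology] = {}
    for _, row in df.iterrows():
        try:
            phys = OrganPhysiology(
                organ_name=str(row["organ"]),
                V_org=float(row["V_org_mL"]),
                V_P_org=float(row["V_P_mL"]),
                V_I_org=float(row["V_I_mL"]),
                mass_fraction=float(row["mass_fraction"]),
            )
        except InvalidPhysiologyError as err:
            raise InvalidPhysiologyError(f"row {row['organ']!r}: {err}") from err
        table[phys.organ_name] = phys
    return table


def write_physiology_table(table: dict[str, OrganPhysiology], path: str | Path) -> None:
    """Write a physiology table back to CSV (round-trips with the loader)."""
    df = pd.DataFrame(
        [
            {
                "organ": p.organ_name,
                "V_org_mL": p.V_org,
                "V_P_mL": p.V_P_org,
                "V_I_mL": p.V_I_org,
                "mass_fraction": p.mass_fraction,
            }
            for p in table.values()
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, index=False)
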