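"""Validated, unit-aware parameter records for the bispecific-antibody model.

The packaged fixture (``data/parameters.yaml``) carries the kinetic rate
constants for the six-variant anti-CD4/CD70 DuetMab panel, the receptor
densities and diffusion coefficients for the three cell types, and the
flow-cytometry assay settings.  Values in the file are stored in the units
of the source table headers; the loader rescales everything to the
canonical (s, dm, mol) system used by the kinetic model.

Species naming convention: target 1 is CD4, target 2 is CD70; the antibody
A binds T1 through arm 1 (k1/k_neg1, volume phase), T2 through arm 2
(k2/k_neg2), and cross-links on the membrane through the surface reactions
3 (AT1 + T2) and 4 (AT2 + T1).
"""

from __future__ import annotations

import dataclasses
import math
from collections import namedtuple
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .units import (
    N_A,
    molecules_per_um2_to_mol_per_dm2,
    sphere_area_um2,
)


class ParameterError(ValueError):
    """Raised when a fixture or rate set violates a model invariant."""


# Scale factors from fixture (table-header) units to absolute SI-style units.
_VOLUME_KON_SCALE = 1e5       # k1, k2 stored as multiples of 1e5 1/(M s)
_KOFF_SCALE = 1e-3            # k_neg* stored as multiples of 1e-3 1/s
_SURFACE_KON_SCALE = 1e13     # k3 stored as multiples of 1e13 dm^2/(mol s)

CELL_TYPES = ("dual_positive", "cd4_only", "cd70_only")


@dataclass(frozen=True)
class KineticConstants:
    """The eight rate constants of the four-reaction binding scheme.

    k1, k2 are volume-phase association constants in 1/(M s); k3, k4 are
    surface cross-linking association constants in dm^2/(mol s); all
    dissociation constants k_neg* are in 1/s.
    """

    variant_name: str
    k1: float
    k_neg1: float
    k2: float
    k_neg2: float
    k3: float
    k_neg3: float
    k4: float
    k_neg4: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_neg1", "k2", "k_neg2", "k3", "k_neg3", "k4", "k_neg4"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ParameterError(
                    f"rate constant {name}={value!r} for variant "
                    f"{self.variant_name!r} must be finite and >= 0"
                )

    @property
    def Kd1(self) -> float:
        """Monovalent dissociation constant of the arm-1 (CD4) interaction, M."""
        return self.k_neg1 / self.k1

    @property
    def Kd2(self) -> float:
        """Monovalent dissociation constant of the arm-2 (CD70) interaction, M."""
        return self.k_neg2 / self.k2

    def replace(self, **changes) -> "KineticConstants":
        return dataclasses.replace(self, **changes)


def validate_rate_set(k: KineticConstants) -> float:
    """Microscopic-reversibility residual of the four-reaction cycle.

    Returns (k1 k_neg2 k3 k_neg4) / (k_neg1 k2 k_neg3 k4).  A value of 1
    means the cycle is thermodynamically consistent: the product of rate
    constants around the closed loop A+T1+T2 -> AT1 -> AT1T2 -> AT2 -> A
    is the same in both directions.
    """
    denom = k.k_neg1 * k.k2 * k.k_neg3 * k.k4
    if denom == 0:
        raise ParameterError(
            f"reversibility residual undefined for {k.variant_name!r}: "
            "k_neg1*k2*k_neg3*k4 = 0"
        )
    return (k.k1 * k.k_neg2 * k.k3 * k.k_neg4) / denom


@dataclass(frozen=True)
class CellSurfaceModel:
    """Receptor numbers and mobility for one spherical model cell."""

    cell_type: str
    n_T1_per_cell: int
    n_T2_per_cell: int
    cell_diameter_um: float
    D_T1_cm2_s: float
    D_T2_cm2_s: float
    D_antibody_cm2_s: float

    def __post_init__(self) -> None:
        if self.n_T1_per_cell < 0 or self.n_T2_per_cell < 0:
            raise ParameterError(f"{self.cell_type}: receptor copy numbers must be >= 0")
        if int(self.n_T1_per_cell) != self.n_T1_per_cell or int(self.n_T2_per_cell) != self.n_T2_per_cell:
            raise ParameterError(f"{self.cell_type}: receptor copy numbers must be integers")
        if self.cell_diameter_um <= 0:
            raise ParameterError(f"{self.cell_type}: cell diameter must be > 0")
        for name in ("D_T1_cm2_s", "D_T2_cm2_s", "D_antibody_cm2_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{self.cell_type}: {name} must be > 0")

    @property
    def surface_area_um2(self) -> float:
        return sphere_area_um2(self.cell_diameter_um)

    @property
    def surface_area_dm2(self) -> float:
        return self.surface_area_um2 * 1e-10

    def total_surface_conc(self, which_target: str) -> float:
        """Total target surface concentration in mol/dm^2."""
        return surface_density(self, which_target).mol_per_dm2


SurfaceDensity = namedtuple("SurfaceDensity", ["per_um2", "mol_per_dm2"])


def surface_density(cells: CellSurfaceModel, which_target: str) -> SurfaceDensity:
    """Uniform target density on the spherical cell, in both unit systems.

    ``which_target`` is "T1" or "T2".  The two returned values are related
    by the Avogadro conversion 1 molecule/um^2 = 1e10/N_A mol/dm^2.
    """
    if which_target == "T1":
        copies = cells.n_T1_per_cell
    elif which_target == "T2":
        copies = cells.n_T2_per_cell
    else:
        raise ParameterError(f"unknown target selector {which_target!r}; use 'T1' or 'T2'")
    area = cells.surface_area_um2
    if area == 0:
        raise ParameterError("cell surface area is zero")
    per_um2 = copies / area
    return SurfaceDensity(per_um2, molecules_per_um2_to_mol_per_dm2(per_um2))


@dataclass(frozen=True)
class AssayConfig:
    """Flow-cytometry assay settings shared by all binding-curve predictions."""

    incubation_time_s: float = 3600.0
    wash_time_s: float = 240.0
    mfi_conversion: float = 1.18  # bound molecules per MFI unit
    antibody_concentrations_M: tuple = ()
    constant_antibody: bool = True

    def __post_init__(self) -> None:
        if self.incubation_time_s < 0 or self.wash_time_s < 0:
            raise ParameterError("assay durations must be >= 0")
        if self.mfi_conversion <= 0:
            raise ParameterError("mfi_conversion must be > 0")
        object.__setattr__(
            self, "antibody_concentrations_M", tuple(self.antibody_concentrations_M)
        )


def default_fixture_path() -> Path:
    return Path(resources.files("bispec").joinpath("data/parameters.yaml"))


def load_raw_fixture(path: str | Path | None = None) -> dict:
    """Parse the fixture file without rescaling (table-header units)."""
    p = Path(path) if path is not None else default_fixture_path()
    if not p.exists():
        raise ParameterError(f"fixture file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    for key in ("variants", "cells", "assay"):
        if key not in raw:
            raise ParameterError(f"fixture {p} is missing top-level key {key!r}")
    return raw


def write_fixture(path: str | Path, raw: Mapping) -> None:
    """Write a raw fixture mapping back to YAML (round-trip safe)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(raw), fh, sort_keys=False)


_VARIANT_KEYS = ("k1", "k_neg1", "k2", "k_neg2", "k3")
_CELL_KEYS = (
    "n_T1_per_cell",
    "n_T2_per_cell",
    "cell_diameter_um",
    "D_T1_cm2_s",
    "D_T2_cm2_s",
    "D_antibody_cm2_s",
)


def load_parameter_fixture(
    path: str | Path | None = None,
) -> tuple[dict[str, KineticConstants], dict[str, CellSurfaceModel], AssayConfig]:
    """Load and validate the full parameter fixture.

    Returns maps variant -> KineticConstants and cell_type -> CellSurfaceModel
    plus the AssayConfig.  Kinetic sets are constructed through the
    microscopic-reversibility closure (k3 = k4, k_neg3 = k_neg2,
    k_neg4 = k_neg1 k2 / k1), so every returned set has reversibility
    residual exactly 1; the tabulated rounded k_neg4 / half-life cells in the
    file are kept only for cross-checks.
    """
    from .rates import close_rate_set  # local import: rates depends on this module

    raw = load_raw_fixture(path)

    variants: dict[str, KineticConstants] = {}
    for name, row in raw["variants"].items():
        for key in _VARIANT_KEYS:
            if key not in row:
                raise ParameterError(f"variant {name!r} is missing key {key!r}")
        k1 = float(row["k1"]) * _VOLUME_KON_SCALE
        k_neg1 = float(row["k_neg1"]) * _KOFF_SCALE
        k2 = float(row["k2"]) * _VOLUME_KON_SCALE
        k_neg2 = float(row["k_neg2"]) * _KOFF_SCALE
        k3 = float(row["k3"]) * _SURFACE_KON_SCALE
        for key, value in (("k1", k1), ("k_neg1", k_neg1), ("k2", k2),
                           ("k_neg2", k_neg2), ("k3", k3)):
            if value < 0:
                raise ParameterError(f"variant {name!r}: {key} = {value} is negative")
        variants[name] = close_rate_set(
            k1=k1, k_neg1=k_neg1, k2=k2, k_neg2=k_neg2,
            k3_equals_k4=k3, variant_name=name,
        )

    cells: dict[str, CellSurfaceModel] = {}
    for cell_type, row in raw["cells"].items():
        for key in _CELL_KEYS:
            if key not in row:
                raise ParameterError(f"cell {cell_type!r} is missing key {key!r}")
        cells[cell_type] = CellSurfaceModel(cell_type=cell_type, **{
            key: (int(row[key]) if key.startswith("n_") else float(row[key]))
            for key in _CELL_KEYS
        })

    a = raw["assay"]
    assay = AssayConfig(
        incubation_time_s=float(a.get("incubation_time_s", 3600.0)),
        wash_time_s=float(a.get("wash_time_s", 240.0)),
        mfi_conversion=float(a.get("mfi_conversion", 1.18)),
        antibody_concentrations_M=tuple(float(c) for c in a.get("antibody_concentrations_M", ())),
        constant_antibody=bool(a.get("constant_antibody", True)),
    )
    return variants, cells, assay


def tabulated_reference(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """The printed derived cells (k_neg4, half-lives) in absolute units,
    for cross-checking against freshly derived values."""
    raw = load_raw_fixture(path)
    out = {}
    for name, row in raw["variants"].items():
        out[name] = {
            "k_neg4": float(row["k_neg4"]) * _KOFF_SCALE,
            "t_half_1": float(row["t_half_1"]),
            "t_half_2": float(row["t_half_2"]),
        }
    return out
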