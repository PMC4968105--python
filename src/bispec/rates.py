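"""Derivation of the unmeasured surface-reaction constants.

Only the volume-phase constants (k1, k_neg1, k2, k_neg2) of the antibody
panel were measured (by surface plasmon resonance).  The surface
cross-linking constants are closed from them and from the membrane
diffusion coefficients:

* the 2D association step is taken as diffusion-limited, kon = 4 (D_a + D_b)
  per molecule pair (Torney-McConnell / Goldstein);
* the four-reaction cycle must satisfy microscopic reversibility,
  k1 k_neg2 k3 k_neg4 = k_neg1 k2 k_neg3 k4;
* one surface off-rate is anchored to its volume-phase value (by default
  k_neg3 = k_neg2, motivated by the small measured surface/volume off-rate
  difference for interferon-receptor binding), which fixes the other one.

This module also houses the geometric helpers for the particle simulator's
cuboid membrane patch (seed counts, box height) and small kinetic
conveniences (Kd, half-life, Einstein displacement time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import CellSurfaceModel, KineticConstants, ParameterError, surface_density
from .units import (
    N_A,
    UM2_PER_CM2,
    UM3_PER_DM3,
    molar_areal_to_per_molecule,
    per_molecule_to_molar_areal,
)


@dataclass(frozen=True)
class DiffusionSpec:
    """A diffusion coefficient tagged with its compartment."""

    D_cm2_s: float
    context: str = "surface"  # "surface" | "volume"

    def __post_init__(self) -> None:
        if self.D_cm2_s <= 0:
            raise ParameterError(f"diffusion coefficient must be > 0, got {self.D_cm2_s}")
        if self.context not in ("surface", "volume"):
            raise ParameterError(f"unknown diffusion context {self.context!r}")

    @property
    def D_um2_s(self) -> float:
        return self.D_cm2_s * UM2_PER_CM2


@dataclass(frozen=True)
class SurfaceRateConstant:
    """A 2D association rate constant in both unit systems.

    value_molar_areal is in dm^2/(mol s) (the ODE system's units),
    value_per_molecule in um^2/(molecule s) (the particle simulator's).
    """

    value_molar_areal: float
    value_per_molecule: float

    def __post_init__(self) -> None:
        if self.value_molar_areal < 0 or self.value_per_molecule < 0:
            raise ParameterError("surface rate constants must be >= 0")
        expect = per_molecule_to_molar_areal(self.value_per_molecule)
        if not math.isclose(self.value_molar_areal, expect, rel_tol=1e-9, abs_tol=1e-300):
            raise ParameterError(
                "inconsistent unit systems: "
                f"{self.value_molar_areal} dm^2/(mol s) vs "
                f"{self.value_per_molecule} um^2/(molecule s)"
            )

    @classmethod
    def from_per_molecule(cls, k_um2: float) -> "SurfaceRateConstant":
        return cls(per_molecule_to_molar_areal(k_um2), k_um2)

    @classmethod
    def from_molar_areal(cls, k_dm2: float) -> "SurfaceRateConstant":
        return cls(k_dm2, molar_areal_to_per_molecule(k_dm2))


def convert_surface_rate(value: float, from_units: str) -> SurfaceRateConstant:
    """Build a SurfaceRateConstant from either unit system.

    ``from_units`` is "per-molecule" (um^2/(molecule s)) or "molar-areal"
    (dm^2/(mol s)).
    """
    if value < 0:
        raise ParameterError("surface rate must be >= 0")
    if from_units == "per-molecule":
        return SurfaceRateConstant.from_per_molecule(value)
    if from_units == "molar-areal":
        return SurfaceRateConstant.from_molar_areal(value)
    raise ParameterError(
        f"unknown unit label {from_units!r}; use 'per-molecule' or 'molar-areal'"
    )


def kon_2d_diffusion_limited(D_a: DiffusionSpec, D_b: DiffusionSpec) -> SurfaceRateConstant:
    """Diffusion-limited 2D association constant kon = 4 (D_a + D_b).

    Both reactants must be membrane-bound; the per-molecule value is in
    um^2/(molecule s) and the molar-areal one follows by Avogadro scaling.
    """
    for spec in (D_a, D_b):
        if spec.context != "surface":
            raise ParameterError(
                "kon = 4D applies to the membrane (2D) compartment only; "
                f"got a {spec.context!r}-context diffusion coefficient"
            )
    k_um2 = 4.0 * (D_a.D_um2_s + D_b.D_um2_s)
    return SurfaceRateConstant.from_per_molecule(k_um2)


def close_rate_set(
    k1: float,
    k_neg1: float,
    k2: float,
    k_neg2: float,
    k3_equals_k4: "SurfaceRateConstant | float",
    anchor: str = "cd70",
    variant_name: str = "custom",
) -> KineticConstants:
    """Close the 8-constant kinetic scheme from the measured volume constants.

    ``k3_equals_k4`` is the common surface association constant (a
    SurfaceRateConstant or a bare number in dm^2/(mol s)).  ``anchor``
    selects which surface off-rate is pinned to its volume-phase value:

    * "cd70" (default): k_neg3 = k_neg2, hence k_neg4 = k_neg1 k2 / k1;
    * "cd4":            k_neg4 = k_neg1, hence k_neg3 = k_neg2 k1 / k2.

    Either way the returned set satisfies the reversibility cycle
    k1 k_neg2 k3 k_neg4 = k_neg1 k2 k_neg3 k4 exactly.
    """
    for name, value in (("k1", k1), ("k_neg1", k_neg1), ("k2", k2), ("k_neg2", k_neg2)):
        if value <= 0:
            raise ParameterError(f"{name} must be > 0, got {value}")
    if isinstance(k3_equals_k4, SurfaceRateConstant):
        k3 = k3_equals_k4.value_molar_areal
    else:
        k3 = float(k3_equals_k4)
    if k3 <= 0:
        raise ParameterError(f"surface association constant must be > 0, got {k3}")

    if anchor == "cd70":
        k_neg3 = k_neg2
        k_neg4 = k_neg1 * k2 / k1
    elif anchor == "cd4":
        k_neg4 = k_neg1
        k_neg3 = k_neg2 * k1 / k2
    else:
        raise ParameterError(f"unknown anchor {anchor!r}; use 'cd70' or 'cd4'")

    return KineticConstants(
        variant_name=variant_name,
        k1=k1, k_neg1=k_neg1, k2=k2, k_neg2=k_neg2,
        k3=k3, k_neg3=k_neg3, k4=k3, k_neg4=k_neg4,
    )


def kd_and_half_life(k_on: float, k_off: float) -> tuple[float, float]:
    """(Kd, t_half) of a monovalent interaction: Kd = koff/kon, t = ln2/koff."""
    if k_on <= 0:
        raise ParameterError(f"k_on must be > 0, got {k_on}")
    if k_off < 0:
        raise ParameterError(f"k_off must be >= 0, got {k_off}")
    kd = k_off / k_on
    t_half = math.inf if k_off == 0 else math.log(2.0) / k_off
    return kd, t_half


def einstein_time_to_displace(D: DiffusionSpec, rms_distance_um: float) -> float:
    """Time for an rms displacement x at coefficient D via x^2 = 2 D t.

    This implements the back-of-envelope mobility convention as stated
    (mean-square displacement 2Dt); the particle simulator itself uses the
    standard per-axis step variance 2 D dt.
    """
    if rms_distance_um < 0:
        raise ParameterError("distance must be >= 0")
    x_cm = rms_distance_um * 1e-4
    return x_cm ** 2 / (2.0 * D.D_cm2_s)


def surface_koff_from_2d_kd(kd_2d_per_um2: float, koff: float) -> SurfaceRateConstant:
    """2D association constant from a surface Kd (molecules/um^2) and koff (1/s).

    kon = koff / Kd_2d in um^2/(molecule s).  This is how the membrane
    chemical-reaction rate for the particle simulator is obtained from the
    CD2-CD58 measurements (Kd ~ 6 molecules/um^2, koff = 5 1/s).
    """
    if kd_2d_per_um2 <= 0:
        raise ParameterError(f"2D Kd must be > 0, got {kd_2d_per_um2}")
    if koff < 0:
        raise ParameterError(f"koff must be >= 0, got {koff}")
    return SurfaceRateConstant.from_per_molecule(koff / kd_2d_per_um2)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cuboid_seed_count(
    cells: CellSurfaceModel, which_target: str, patch_area_um2: float = 0.1
) -> int:
    """Number of target molecules seeded on the simulation patch.

    Nearest integer (ties away from zero) of cell-surface density times
    patch area; deterministic.
    """
    if patch_area_um2 <= 0:
        raise ParameterError("patch area must be > 0")
    density = surface_density(cells, which_target).per_um2
    return _round_half_away(density * patch_area_um2)


def cuboid_height_for_concentration(
    n_molecules: int, concentration_M: float, patch_area_um2: float = 0.1
) -> float:
    """Cuboid height (um) holding n antibody molecules at a molar concentration.

    h = n / (N_A * c * A); c in mol/dm^3, A in um^2, volume converted via
    1 dm^3 = 1e15 um^3.
    """
    if concentration_M <= 0:
        raise ParameterError("concentration must be > 0")
    if patch_area_um2 <= 0:
        raise ParameterError("patch area must be > 0")
    if n_molecules < 0:
        raise ParameterError("molecule count must be >= 0")
    volume_dm3 = n_molecules / (N_A * concentration_M)
    return volume_dm3 * UM3_PER_DM3 / patch_area_um2
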