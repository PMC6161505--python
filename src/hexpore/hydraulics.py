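"""Analytic Stokes-regime hydraulics of a micropore-array membrane.

Each hexagonal pore is mapped to the circular pore of equal open area
(``r_eq = √(A_hex/π)``, ``A_hex = (3√3/8)·d²``) and its hydraulic resistance
taken as the Dagan orifice-plus-channel closed form

    R₁ = (μ_f / r_eq³) · (3 + 8·h/(π·r_eq))        [Pa·s·m⁻³]

which combines the Sampson entrance/exit loss (both ends counted once in the
``3μ/r³`` term) with the finite-length Poiseuille channel through the
membrane thickness ``h``.  Identical pores act in parallel, so a membrane of
``n`` pores has resistance ``R₁/n`` and the pressure-flow relation stays
linear (creeping flow).  This is a deliberate analytic approximation of the
full finite-element flow field: it preserves the scalings and the ordering
of designs by porosity, which is what the design comparisons need.

SI units throughout (m, m³/s, Pa); geometry specs carry μm and are converted
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import SQRT3, HexPoreSpec, pore_density

G_STANDARD = 9.80665  # m/s², standard gravity


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian working fluid (defaults: water / PBS at room temperature)."""

    viscosity: float = 1.0e-3  # Pa·s
    density: float = 1000.0  # kg/m³

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")


@dataclass(frozen=True)
class MembraneHydraulics:
    """A pore-array membrane as a parallel network of identical pores.

    ``effective_span`` is the side of the square effective filtration area
    (default 13 mm); the pore count is the design pore density times that
    area.
    """

    spec: HexPoreSpec
    effective_span: float = 13e-3  # m

    def __post_init__(self) -> None:
        if not self.effective_span > 0:
            raise ValueError(f"span must be positive, got {self.effective_span}")

    @property
    def area(self) -> float:
        """Effective filtration area, m²."""
        return self.effective_span**2

    @property
    def n_pores(self) -> int:
        """Number of pores on the effective area (at least 1)."""
        area_mm2 = self.area * 1e6
        return max(1, int(pore_density(self.spec) * area_mm2))


def equivalent_pore_radius(spec: HexPoreSpec) -> float:
    """Radius (m) of the circular pore with the same open area as the hexagon."""
    a_hex_um2 = (3.0 * SQRT3 / 8.0) * spec.d**2
    return math.sqrt(a_hex_um2 / math.pi) * 1e-6


def pore_resistance(spec: HexPoreSpec, fluid: FluidSpec = FluidSpec()) -> float:
    """Hydraulic resistance of a single pore, Pa·s/m³."""
    r = equivalent_pore_radius(spec)
    h = spec.h * 1e-6
    return (fluid.viscosity / r**3) * (3.0 + 8.0 * h / (math.pi * r))


def membrane_pressure_drop(
    mem: MembraneHydraulics, Q: float, fluid: FluidSpec = FluidSpec()
) -> float:
    """Pressure drop (Pa) across the membrane at total throughput ``Q`` (m³/s)."""
    if Q < 0:
        raise ValueError(f"throughput must be nonnegative, got {Q}")
    return Q * pore_resistance(mem.spec, fluid) / mem.n_pores


def gravity_throughput(
    mem: MembraneHydraulics, head: float, fluid: FluidSpec = FluidSpec()
) -> float:
    """Gravity-driven throughput (m³/s) under a liquid head of height ``head`` (m)."""
    if head < 0:
        raise ValueError(f"head must be nonnegative, got {head}")
    dp = fluid.density * G_STANDARD * head
    return dp * mem.n_pores / pore_resistance(mem.spec, fluid)


def mean_wall_shear(
    spec: HexPoreSpec, per_pore_Q: float, fluid: FluidSpec = FluidSpec()
) -> float:
    """Poiseuille wall shear stress (Pa) in the equivalent circular pore.

    τ_w = 4·μ_f·Q_pore / (π·r_eq³) for fully developed tube flow.
    """
    if per_pore_Q < 0:
        raise ValueError(f"per-pore flow must be nonnegative, got {per_pore_Q}")
    r = equivalent_pore_radius(spec)
    return 4.0 * fluid.viscosity * per_pore_Q / (math.pi * r**3)


def time_to_filter(volume: float, Q: float) -> float:
    """Time (s) to pass ``volume`` (m³) at constant throughput ``Q`` (m³/s)."""
    if volume < 0:
        raise ValueError(f"volume must be nonnegative, got {volume}")
    if not Q > 0:
        raise ValueError(f"throughput must be positive, got {Q}")
    return volume / Q


def ml_per_min(Q_m3_s: float) -> float:
    """Convert a throughput from m³/s to mL/min."""
    return Q_m3_s * 1e6 * 60.0
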