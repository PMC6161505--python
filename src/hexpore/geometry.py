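"""Closed-form design geometry of close-packed hexagonal micropore arrays.

A membrane consists of regular hexagonal pores (vertex-to-vertex diagonal
``d``, flat-to-flat width ``d' = d·√3/2``) tiled on a hexagonal lattice with
an edge-to-edge inter-pore wall of width ``s``.  The tiling cell is the
concentric regular hexagon of flat-to-flat width ``d' + s`` (the
center-to-center pitch), so the open-area fraction is the squared linear
ratio ``(d'/(d'+s))²``.

All lengths in this module are micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class HexPoreSpec:
    """Design specification of one hexagonal micropore array.

    Parameters
    ----------
    d : float
        Pore diagonal (vertex-to-vertex) length, μm.
    s : float
        Edge-to-edge space between adjacent pores, μm.
    h : float
        Membrane thickness, μm (default 10).
    label : str
        Free-text case identifier.
    """

    d: float
    s: float
    h: float = 10.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"pore diagonal d must be positive, got {self.d}")
        if self.s < 0:
            raise ValueError(f"inter-pore space s must be >= 0, got {self.s}")
        if not self.h > 0:
            raise ValueError(f"membrane thickness h must be positive, got {self.h}")

    @property
    def flat_to_flat(self) -> float:
        """Flat-to-flat (edge-to-edge) pore width d' = d·√3/2, μm."""
        return flat_to_flat(self.d)

    @property
    def pitch_um(self) -> float:
        return pitch(self)

    @property
    def porosity(self) -> float:
        return porosity(self)


def flat_to_flat(d: float) -> float:
    """Flat-to-flat width d' of a regular hexagon with diagonal ``d``.

    For a regular hexagon the edge-to-edge width is ``d·√3/2 < d``.
    """
    if not d > 0:
        raise ValueError(f"diagonal must be positive, got {d}")
    return d * SQRT3 / 2.0


def pitch(spec: HexPoreSpec) -> float:
    """Center-to-center pitch of the close-packed array: d' + s, μm.

    This is also the flat-to-flat width of the hexagonal tiling cell.
    """
    return spec.flat_to_flat + spec.s


def porosity(spec: HexPoreSpec) -> float:
    """Open-area fraction of the membrane, in (0, 1].

    Pore and tiling-cell hexagons are concentric and similar, so the area
    ratio is the squared linear ratio ``(d'/(d'+s))²``.
    """
    r = spec.flat_to_flat / pitch(spec)
    return r * r


def porosity_percent(spec: HexPoreSpec, ndigits: int = 2) -> float:
    """Porosity expressed in percent, rounded (default 2 decimal places)."""
    return round(100.0 * porosity(spec), ndigits)


def pore_density(spec: HexPoreSpec) -> float:
    """Number of pores per unit membrane area, mm⁻².

    One pore per tiling cell of area ``(√3/2)·(d'+s)²``.
    """
    p = pitch(spec)
    cell_area_um2 = (SQRT3 / 2.0) * p * p
    return 1.0e6 / cell_area_um2  # 1 mm² = 1e6 μm²


def aspect_ratio(depth: float, width: float) -> float:
    """Thickness-to-width (aspect) ratio of a trench or pore, dimensionless."""
    if not depth > 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if not width > 0:
        raise ValueError(f"width must be positive, got {width}")
    return depth / width


def design_space_for_porosity(d: float, target: float) -> float:
    """Inverse design: the space ``s`` giving a target porosity at diagonal ``d``.

    Solves ``(d'/(d'+s))² = target`` for ``s``:  ``s = d'·(1/√target − 1)``.
    """
    if not 0 < target < 1:
        raise ValueError(f"target porosity must lie in (0, 1), got {target}")
    dprime = flat_to_flat(d)
    return dprime * (1.0 / math.sqrt(target) - 1.0)


def square_pore_porosity(width: float, s: float) -> float:
    """Open-area fraction of a square-pore array with pore width and space, (0, 1]."""
    if not width > 0:
        raise ValueError(f"pore width must be positive, got {width}")
    if s < 0:
        raise ValueError(f"space must be >= 0, got {s}")
    r = width / (width + s)
    return r * r
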