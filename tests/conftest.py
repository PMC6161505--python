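"""Shared fixtures and independent geometric/numerical oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from hexpore import HexPoreSpec, PlateSystem
from hexpore.io import load_table2_fixture

SQRT3 = math.sqrt(3.0)


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture
def plate():
    """Flat-film reference system: E = 3.01 GPa, μ = 0.5, h = 10 μm, a = 6.5 mm."""
    return PlateSystem(E=3.01e9, mu=0.5, h=10e-6, a=6.5e-3)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)


def in_hexagon(x: np.ndarray, y: np.ndarray, width: float) -> np.ndarray:
    """Point-in-regular-hexagon test, flat-to-flat ``width``, flats facing ±x."""
    q = width / 2.0
    return (
        (np.abs(x) <= q)
        & (np.abs(0.5 * x + (SQRT3 / 2.0) * y) <= q)
        & (np.abs(0.5 * x - (SQRT3 / 2.0) * y) <= q)
    )


def mc_porosity(spec: HexPoreSpec, n_points: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo rejection estimate of open-area fraction and its sd.

    Samples uniformly over one rectangular period of the hexagonal lattice
    (width p, height √3·p, two pore centers) and counts hits inside any pore
    hexagon, testing the five centers whose hexagons can intersect the
    rectangle.
    """
    p = spec.flat_to_flat + spec.s
    w = spec.flat_to_flat
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, p, n_points)
    y = rng.uniform(0.0, SQRT3 * p, n_points)
    centers = [
        (0.0, 0.0),
        (p, 0.0),
        (0.0, SQRT3 * p),
        (p, SQRT3 * p),
        (p / 2.0, SQRT3 * p / 2.0),
    ]
    hit = np.zeros(n_points, dtype=bool)
    for cx, cy in centers:
        hit |= in_hexagon(x - cx, y - cy, w)
    frac = hit.mean()
    sd = math.sqrt(frac * (1.0 - frac) / n_points)
    return float(frac), sd


def lattice_count_density(pitch_um: float, n_rows: int = 200) -> float:
    """Pore density (mm⁻²) by counting hexagonal-lattice centers in a square.

    Rows are √3/2·pitch apart with alternate rows offset by pitch/2; centers
    inside an L×L window are counted and divided by the window area.
    """
    row_h = pitch_um * SQRT3 / 2.0
    L = n_rows * row_h
    count = 0
    j = 0
    yy = 0.0
    while yy < L:
        offset = (j % 2) * pitch_um / 2.0
        count += len(np.arange(offset, L, pitch_um))
        j += 1
        yy = j * row_h
    return count / (L * L) * 1e6  # per mm²


def bisect_deflection(alpha: float, beta: float, rhs: float) -> float:
    """Root of alpha·x³ + beta·x = rhs by bracketing bisection (scipy brentq)."""
    if rhs == 0.0:
        return 0.0
    hi = 1e-9
    while alpha * hi**3 + beta * hi < rhs:
        hi *= 2.0
    return brentq(
        lambda x: alpha * x**3 + beta * x - rhs, 0.0, hi, xtol=1e-30, rtol=1e-15
    )


def oracle_deflection_concentrated(sys: PlateSystem, q_c: float) -> float:
    c3 = (353.0 - 191.0 * sys.mu) / (648.0 * (1.0 - sys.mu))
    c1 = 4.0 / (3.0 * (1.0 - sys.mu))
    return bisect_deflection(
        c3 * sys.E * sys.h, c1 * sys.E * sys.h**3, q_c * sys.a**2 / math.pi
    )


def oracle_deflection_uniform(sys: PlateSystem, q_u: float) -> float:
    c3 = (23.0 - 9.0 * sys.mu) / (252.0 * (1.0 - sys.mu))
    c1 = 2.0 / (9.0 * (1.0 - sys.mu))
    return bisect_deflection(
        c3 * sys.E * sys.h, c1 * sys.E * sys.h**3, q_u * sys.a**2 / 24.0
    )
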