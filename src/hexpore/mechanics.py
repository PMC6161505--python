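"""Large-deflection mechanics of a clamped membrane plate.

The membrane is modelled as a clamped circular plate in the large-deflection
(membrane-stretching) regime.  For a concentrated center load ``q_c`` (total
force, N) the center deflection ``d_v`` satisfies the cubic

    (353 − 191μ)/(648(1 − μ)) · E·h·d_v³ + 4·E·h³·d_v / (3(1 − μ)) = q_c·a²/π

and for a uniformly distributed total load ``q_u``

    (23 − 9μ)/(252(1 − μ)) · E·h·d_v³ + 2·E·h³·d_v / (9(1 − μ)) = q_u·a²/24,

with ``E`` the equivalent Young's modulus, ``μ`` the Poisson ratio, ``h`` the
thickness and ``a`` the effective clamped radius.  Both load-deflection laws
are linear in ``E``, which makes equivalent-modulus extraction from measured
load-deflection pairs an exact slope-through-origin least-squares problem.

The radial stretch of the deflected membrane is taken from the chord-to-arc
geometry: relative elongation ``δ = √(a² + d_v²)/a − 1``, and the lateral
size change of a pore of diameter ``d_p`` is ``δ·d_p``.

All quantities in this module are SI (m, N, Pa); pore diameters passed to
:func:`pore_size_change` are μm and the returned size change is nm, matching
how these quantities are usually reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PlateSystem",
    "LoadDeflectionSeries",
    "DeformationResult",
    "DegenerateFitError",
    "concentrated_load_for_deflection",
    "deflection_under_concentrated_load",
    "deflection_under_uniform_load",
    "fit_equivalent_modulus",
    "elongation",
    "pore_size_change",
    "predict_filtration_deformation",
    "pressure_to_load",
]


class DegenerateFitError(ValueError):
    """Raised when a load-deflection series cannot identify the modulus."""


@dataclass(frozen=True)
class PlateSystem:
    """Elastic parameters of a clamped membrane.

    Parameters
    ----------
    E : float
        Equivalent Young's modulus, Pa.
    mu : float
        Poisson ratio, dimensionless (0.5 for Parylene C).
    h : float
        Membrane thickness, m.
    a : float
        Effective clamped radius, m (half the effective filtration span).
    """

    E: float
    mu: float = 0.5
    h: float = 10e-6
    a: float = 6.5e-3

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"modulus E must be positive, got {self.E}")
        if not 0 < self.mu < 1:
            raise ValueError(f"Poisson ratio must lie in (0, 1), got {self.mu}")
        if not self.h > 0:
            raise ValueError(f"thickness h must be positive, got {self.h}")
        if not self.a > self.h:
            raise ValueError(f"radius a={self.a} must exceed thickness h={self.h}")


@dataclass
class LoadDeflectionSeries:
    """Paired (total load, center deflection) measurements.

    loads are N, deflections are m.  A monotone-consistency check warns when
    strictly increasing loads do not produce strictly increasing deflections
    (possible measurement problem); it never raises.
    """

    loads: np.ndarray
    deflections: np.ndarray

    def __init__(self, loads: Sequence[float], deflections: Sequence[float]):
        loads = np.asarray(loads, dtype=float)
        deflections = np.asarray(deflections, dtype=float)
        if loads.shape != deflections.shape or loads.ndim != 1:
            raise ValueError("loads and deflections must be 1-D of equal length")
        if len(loads) < 2:
            raise ValueError("need at least 2 points for fitting")
        if np.any(loads < 0) or np.any(deflections < 0):
            raise ValueError("loads and deflections must be nonnegative")
        if np.all(np.diff(loads) > 0) and not np.all(np.diff(deflections) > 0):
            warnings.warn(
                "strictly increasing loads but non-increasing deflections: "
                "series is not monotone-consistent",
                stacklevel=2,
            )
        self.loads = loads
        self.deflections = deflections

    def __len__(self) -> int:
        return len(self.loads)


@dataclass(frozen=True)
class DeformationResult:
    """Predicted membrane deformation under one filtration load."""

    d_v: float  # center deflection, m
    delta: float  # relative radial elongation, dimensionless
    pore_change_nm: float  # absolute pore-size variation, nm
    load: float  # applied total load, N


def _cubic_coeffs_concentrated(sys: PlateSystem) -> tuple[float, float]:
    """(cubic, linear) coefficients of the concentrated-load law in d_v."""
    c3 = (353.0 - 191.0 * sys.mu) / (648.0 * (1.0 - sys.mu))
    c1 = 4.0 / (3.0 * (1.0 - sys.mu))
    return c3 * sys.E * sys.h, c1 * sys.E * sys.h**3


def _cubic_coeffs_uniform(sys: PlateSystem) -> tuple[float, float]:
    c3 = (23.0 - 9.0 * sys.mu) / (252.0 * (1.0 - sys.mu))
    c1 = 2.0 / (9.0 * (1.0 - sys.mu))
    return c3 * sys.E * sys.h, c1 * sys.E * sys.h**3


def _solve_depressed_cubic(alpha: float, beta: float, rhs: float) -> float:
    """Unique nonnegative root of ``alpha·x³ + beta·x = rhs`` (alpha, beta > 0).

    Uses the hyperbolic closed form, numerically stable for all rhs ≥ 0:
    with p = beta/alpha and q = rhs/alpha, the root of x³ + p·x = q is
    ``x = 2·√(p/3)·sinh(asinh(3q/(2p)·√(3/p)) / 3)`` — monotone in q, no
    cancellation in either the small-load (linear) or large-load (cubic)
    limit.
    """
    if rhs == 0.0:
        return 0.0
    p = beta / alpha
    q = rhs / alpha
    sp3 = math.sqrt(p / 3.0)
    return 2.0 * sp3 * math.sinh(math.asinh(3.0 * q / (2.0 * p * sp3)) / 3.0)


def concentrated_load_for_deflection(sys: PlateSystem, d_v: float) -> float:
    """Total concentrated center load (N) producing deflection ``d_v`` (m)."""
    if d_v < 0:
        raise ValueError(f"deflection must be nonnegative, got {d_v}")
    A, B = _cubic_coeffs_concentrated(sys)
    return (math.pi / sys.a**2) * (A * d_v**3 + B * d_v)


def uniform_load_for_deflection(sys: PlateSystem, d_v: float) -> float:
    """Total uniformly distributed load (N) producing deflection ``d_v`` (m)."""
    if d_v < 0:
        raise ValueError(f"deflection must be nonnegative, got {d_v}")
    A, B = _cubic_coeffs_uniform(sys)
    return (24.0 / sys.a**2) * (A * d_v**3 + B * d_v)


def deflection_under_concentrated_load(sys: PlateSystem, q_c: float) -> float:
    """Center deflection (m) under total concentrated load ``q_c`` (N)."""
    if q_c < 0:
        raise ValueError(f"load must be nonnegative, got {q_c}")
    A, B = _cubic_coeffs_concentrated(sys)
    return _solve_depressed_cubic(A, B, q_c * sys.a**2 / math.pi)


def deflection_under_uniform_load(sys: PlateSystem, q_u: float) -> float:
    """Center deflection (m) under total uniformly distributed load ``q_u`` (N)."""
    if q_u < 0:
        raise ValueError(f"load must be nonnegative, got {q_u}")
    A, B = _cubic_coeffs_uniform(sys)
    return _solve_depressed_cubic(A, B, q_u * sys.a**2 / 24.0)


def geometry_factor(
    d_v: np.ndarray | float, mu: float, h: float, a: float
) -> np.ndarray | float:
    """Load per unit modulus: f(d_v) such that q_c = E·f(d_v).

    The bracketed geometry term of the concentrated-load law divided by E;
    the modulus fit is a straight line through the origin in this variable.
    """
    c3 = (353.0 - 191.0 * mu) / (648.0 * (1.0 - mu))
    c1 = 4.0 / (3.0 * (1.0 - mu))
    d_v = np.asarray(d_v, dtype=float)
    return (math.pi / a**2) * (c3 * h * d_v**3 + c1 * h**3 * d_v)


def fit_equivalent_modulus(
    series: LoadDeflectionSeries, mu: float = 0.5, h: float = 10e-6, a: float = 6.5e-3
) -> tuple[float, float]:
    """Equivalent Young's modulus from a load-deflection series.

    The concentrated-load law is linear in ``E`` (``q_i = E·f(d_v,i)`` with
    ``f`` the geometry factor), so the fit is an exact closed-form
    through-origin slope — deterministic, no initialization.  Because the
    measured (noisy) quantity is the deflection, i.e. the regressor ``f``
    rather than the load, the naive slope ``Σf·q/Σf²`` is attenuation-biased
    (errors-in-variables); the inverse-regression slope

        Ê = Σ q_i² / Σ f_i·q_i

    cancels that attenuation at leading order while remaining exact on
    noiseless data.  The standard error propagates the residual variance of
    the implied relative deflection errors through the sensitivity of ``f``
    to a relative deflection perturbation (delta method) — the error model
    under which the synthetic series are generated and optical displacement
    measurements are usually reported.

    Returns
    -------
    (E, stderr) : tuple of float, both Pa.
    """
    f = np.asarray(geometry_factor(series.deflections, mu, h, a))
    q = series.loads
    cross = float(np.sum(f * q))
    ssq = float(np.sum(q * q))
    if cross == 0.0 or ssq == 0.0:
        raise DegenerateFitError(
            "degenerate series (zero deflections or loads): modulus unidentifiable"
        )
    e_hat = ssq / cross
    # sensitivity of f to a relative deflection error: u = d f / d(log d_v)
    c3 = (353.0 - 191.0 * mu) / (648.0 * (1.0 - mu))
    c1 = 4.0 / (3.0 * (1.0 - mu))
    d_v = series.deflections
    u = (math.pi / a**2) * (3.0 * c3 * h * d_v**3 + c1 * h**3 * d_v)
    resid = f - q / e_hat
    ok = u > 0
    n_ok = int(np.sum(ok))
    if n_ok < 2:
        raise DegenerateFitError("need at least 2 nonzero-deflection points")
    sigma2_rel = float(np.sum((resid[ok] / u[ok]) ** 2)) / (n_ok - 1)
    var = (e_hat**2 / ssq) ** 2 * sigma2_rel * float(np.sum((q * u) ** 2))
    stderr = math.sqrt(var)
    return e_hat, stderr


def elongation(a: float, d_v: float) -> float:
    """Relative radial elongation δ = √(a² + d_v²)/a − 1 of the deflected span.

    Evaluated as ``x²/(1 + √(1+x²))`` with ``x = d_v/a``, exact and stable
    for small deflections (δ → x²/2).
    """
    if not a > 0:
        raise ValueError(f"half-span a must be positive, got {a}")
    if d_v < 0:
        raise ValueError(f"deflection must be nonnegative, got {d_v}")
    x = d_v / a
    x2 = x * x
    return x2 / (1.0 + math.sqrt(1.0 + x2))


def pore_size_change(delta: float, pore_d_um: float) -> float:
    """Absolute lateral pore-size variation, nm, for elongation ``delta``.

    The membrane stretches uniformly in-plane, so a pore of diameter
    ``pore_d_um`` (μm) widens by ``delta · pore_d_um`` (returned in nm).
    """
    if delta < 0:
        raise ValueError(f"elongation must be nonnegative, got {delta}")
    if not pore_d_um > 0:
        raise ValueError(f"pore diameter must be positive, got {pore_d_um}")
    return delta * pore_d_um * 1e3


def predict_filtration_deformation(
    sys: PlateSystem, pore_d_um: float, q_u: float
) -> DeformationResult:
    """Deformation of a loaded membrane: deflection, elongation, pore change.

    Chains the uniform-load deflection solve, the elongation geometry and
    the pore-size scaling into one record for a filtration-pressure load.
    """
    d_v = deflection_under_uniform_load(sys, q_u)
    delta = elongation(sys.a, d_v)
    change = pore_size_change(delta, pore_d_um)
    return DeformationResult(d_v=d_v, delta=delta, pore_change_nm=change, load=q_u)


def pressure_to_load(pressure_pa: float, span_m: float) -> float:
    """Total force (N) of a uniform pressure over a square loaded span."""
    if pressure_pa < 0:
        raise ValueError(f"pressure must be nonnegative, got {pressure_pa}")
    if not span_m > 0:
        raise ValueError(f"span must be positive, got {span_m}")
    return pressure_pa * span_m * span_m
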