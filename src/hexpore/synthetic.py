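"""Seeded generators for every input the analysis pipeline consumes.

Emulated study conditions:

* **Load-deflection curves** — center deflections solving the concentrated-
  load plate cubic exactly for a known modulus, then perturbed by
  multiplicative Gaussian noise on the deflection (the measured quantity in
  an optical-displacement setup).
* **Bead mixtures** — monodispersed polystyrene size standards at nominal
  9 μm and 12 μm (2 % CV, truncated normal), at the loading of the
  single-layer experiment: 8.1×10⁴/mL and 2.9×10⁴/mL in 3 mL, i.e. 243 000
  and 87 000 beads (3.3×10⁵ total); and a multi-dispersed load drawn
  uniformly over 6-22 μm (4.5×10⁶ beads in the multi-layer experiment).
* **T24 bladder-cancer cell sizes** — truncated normal, mean 13.5 μm,
  sd 0.84 μm, truncated to the observed 8-20 μm range.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mechanics import LoadDeflectionSeries, PlateSystem, concentrated_load_for_deflection
from .sieve import ParticlePopulation

MAX_REJECTION_ATTEMPTS = 1000

# T24 cell size statistics (μm), measured in PBS suspension
T24_MEAN_UM = 13.5
T24_SD_UM = 0.84
T24_RANGE_UM = (8.0, 20.0)

# monosized PS bead standards: vendor-typical 2 % coefficient of variation
BEAD_CV = 0.02


@dataclass(frozen=True)
class MixtureComponentSpec:
    """One component of a particle-size mixture (sizes in μm)."""

    mean: float
    sd: float
    count: int
    lower: float | None = None
    upper: float | None = None
    distribution: str = "truncated-normal"
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError(
                    f"truncation window [{self.lower}, {self.upper}] is empty"
                )
        if self.distribution not in ("truncated-normal", "uniform"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def _rejection_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Truncated-normal draws by rejection (capped attempts per draw)."""
    if n == 0:
        return np.empty(0)
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ValueError(
                f"degenerate component mean {mean} outside window [{lo}, {hi}]"
            )
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    for _ in range(MAX_REJECTION_ATTEMPTS):
        draw = rng.normal(mean, sd, size=n - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
        if filled == n:
            return out
    raise ValueError(
        f"rejection sampling failed: window [{lo}, {hi}] too improbable for "
        f"N({mean}, {sd}²)"
    )


def sample_component(
    spec: MixtureComponentSpec, rng: np.random.Generator
) -> np.ndarray:
    """Diameters (μm) for one mixture component, exact count."""
    if spec.distribution == "uniform":
        lo = spec.lower if spec.lower is not None else spec.mean - spec.sd
        hi = spec.upper if spec.upper is not None else spec.mean + spec.sd
        return rng.uniform(lo, hi, size=spec.count)
    lo = spec.lower if spec.lower is not None else 0.0
    hi = spec.upper if spec.upper is not None else np.inf
    return _rejection_truncated_normal(rng, spec.mean, spec.sd, lo, hi, spec.count)


def gen_bead_mixture(
    components: Sequence[MixtureComponentSpec], seed: int
) -> ParticlePopulation:
    """Mixture population with exact per-component counts, seeded."""
    rng = np.random.default_rng(seed)
    diameters, labels = [], []
    for comp in components:
        draws = sample_component(comp, rng)
        diameters.append(draws)
        labels.append(np.full(len(draws), comp.label, dtype=object))
    if not diameters or sum(map(len, diameters)) == 0:
        pop = ParticlePopulation.__new__(ParticlePopulation)
        pop.diameters = np.empty(0)
        pop.labels = np.empty(0, dtype=object)
        return pop
    return ParticlePopulation(np.concatenate(diameters), np.concatenate(labels))


def single_layer_bead_components() -> list[MixtureComponentSpec]:
    """The 9/12 μm monodispersed mixture of the single-layer experiment.

    Stock concentrations 8.1×10⁴/mL and 2.9×10⁴/mL loaded as 3 mL.
    """
    return [
        MixtureComponentSpec(9.0, 9.0 * BEAD_CV, 243_000, label="9um"),
        MixtureComponentSpec(12.0, 12.0 * BEAD_CV, 87_000, label="12um"),
    ]


def multi_layer_bead_components(n: int = 4_500_000) -> list[MixtureComponentSpec]:
    """Multi-dispersed 6-22 μm load of the multi-layer experiment (uniform)."""
    return [
        MixtureComponentSpec(
            14.0, 0.0, n, lower=6.0, upper=22.0, distribution="uniform", label="mix"
        )
    ]


def gen_cell_sizes(n: int, seed: int) -> ParticlePopulation:
    """T24 cell diameters: truncated normal 13.5 ± 0.84 μm on [8, 20] μm."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    lo, hi = T24_RANGE_UM
    draws = _rejection_truncated_normal(rng, T24_MEAN_UM, T24_SD_UM, lo, hi, n)
    pop = ParticlePopulation.__new__(ParticlePopulation)
    pop.diameters = draws
    pop.labels = np.full(n, "T24", dtype=object)
    return pop


def default_deflection_targets(h: float, n: int = 20) -> np.ndarray:
    """Default measurement schedule: deflections spanning 0.1h to 1.0h (m).

    Deflections up to about one membrane thickness keep the test
    non-destructive while exercising both the bending (linear) and
    stretching (cubic) terms of the plate law.
    """
    return np.linspace(0.1 * h, 1.0 * h, n)


def gen_load_deflection(
    E_true: float,
    mu: float = 0.5,
    h: float = 10e-6,
    a: float = 6.5e-3,
    loads: Sequence[float] | None = None,
    n: int = 20,
    noise_sd_rel: float = 0.05,
    seed: int = 0,
) -> LoadDeflectionSeries:
    """Synthetic load-deflection series from the concentrated-load plate law.

    Noiseless deflections solve the plate cubic exactly at ``E_true``; the
    recorded deflection is then multiplied by ``(1 + N(0, noise_sd_rel))``.
    If ``loads`` is omitted, loads are chosen so the noiseless deflections
    follow :func:`default_deflection_targets`.
    """
    if noise_sd_rel < 0:
        raise ValueError(f"noise level must be >= 0, got {noise_sd_rel}")
    sys = PlateSystem(E=E_true, mu=mu, h=h, a=a)
    if loads is None:
        targets = default_deflection_targets(h, n)
        loads = np.array(
            [concentrated_load_for_deflection(sys, d) for d in targets]
        )
        deflections = targets.copy()
    else:
        from .mechanics import deflection_under_concentrated_load

        loads = np.asarray(loads, dtype=float)
        deflections = np.array(
            [deflection_under_concentrated_load(sys, q) for q in loads]
        )
    rng = np.random.default_rng(seed)
    noisy = deflections * (1.0 + rng.normal(0.0, noise_sd_rel, size=len(deflections)))
    return LoadDeflectionSeries(loads, np.clip(noisy, 0.0, None))
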