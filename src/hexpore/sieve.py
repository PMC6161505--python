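"""Deterministic size-cutoff sieving of particle populations.

A rigid sphere passes a hexagonal pore iff its diameter is strictly smaller
than the pore's flat-to-flat width d' (ties are retained — the conservative
sieve).  A stack of membranes with strictly decreasing cutoffs fractionates
a polydisperse load: the particles trapped on layer i are exactly those with
d'_i ≤ diameter < d'_{i−1}, and the filtrate is everything below the last
cutoff.  Particle counts are conserved exactly.

Cells can squeeze through pores smaller than their nominal diameter; an
optional logistic "softness" pass-probability is provided for that regime
but is OFF by default (rigid-sphere behaviour).

Diameters and cutoffs are μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ParticlePopulation",
    "MembraneStack",
    "FiltrationOutcome",
    "passes",
    "filter_single",
    "filter_stack",
    "recovery_rate",
    "recovery_summary",
    "size_histogram",
]


@dataclass
class ParticlePopulation:
    """A collection of particle diameters (μm) with optional component labels."""

    diameters: np.ndarray
    labels: np.ndarray | None = None

    def __init__(
        self,
        diameters: Sequence[float],
        labels: Sequence[str] | None = None,
    ):
        diameters = np.asarray(diameters, dtype=float)
        if diameters.ndim != 1:
            raise ValueError("diameters must be 1-D")
        if np.any(diameters <= 0):
            raise ValueError("all particle diameters must be positive")
        if labels is not None:
            labels = np.asarray(labels, dtype=object)
            if labels.shape != diameters.shape:
                raise ValueError("labels must match diameters in length")
        self.diameters = diameters
        self.labels = labels

    def __len__(self) -> int:
        return len(self.diameters)

    def subset(self, mask: np.ndarray) -> "ParticlePopulation":
        labels = self.labels[mask] if self.labels is not None else None
        return ParticlePopulation(self.diameters[mask], labels)

    def count_label(self, label: str) -> int:
        if self.labels is None:
            return 0
        return int(np.sum(self.labels == label))

    @staticmethod
    def concatenate(pops: Sequence["ParticlePopulation"]) -> "ParticlePopulation":
        pops = [p for p in pops if len(p) > 0]
        if not pops:
            return ParticlePopulation(np.empty(0))
        diam = np.concatenate([p.diameters for p in pops])
        if all(p.labels is not None for p in pops):
            labels = np.concatenate([p.labels for p in pops])
        else:
            labels = None
        return ParticlePopulation(diam, labels)


# empty populations bypass the positivity check via __new__-style construction
def _empty_population(labelled: bool) -> ParticlePopulation:
    pop = ParticlePopulation.__new__(ParticlePopulation)
    pop.diameters = np.empty(0, dtype=float)
    pop.labels = np.empty(0, dtype=object) if labelled else None
    return pop


@dataclass
class MembraneStack:
    """Ordered cutoff widths d'_i (μm), top to bottom.

    Fractionation requires strictly decreasing cutoffs; a violation only
    warns (the stack still filters, but layer ranges overlap).
    """

    cutoffs: list[float]

    def __post_init__(self) -> None:
        if not self.cutoffs:
            raise ValueError("stack needs at least one layer")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("all cutoffs must be positive")
        if any(b >= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            warnings.warn(
                "stack cutoffs are not strictly decreasing: layers will not "
                "fractionate into disjoint size ranges",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.cutoffs)


@dataclass
class FiltrationOutcome:
    """Per-layer retained populations, the filtrate, and summary statistics."""

    retained: list[ParticlePopulation]
    filtrate: ParticlePopulation
    cutoffs: list[float]

    @property
    def layer_counts(self) -> list[int]:
        return [len(p) for p in self.retained]

    @property
    def n_input(self) -> int:
        return sum(self.layer_counts) + len(self.filtrate)

    def recovery(self, label: str) -> float:
        """Fraction of particles with ``label`` retained on any layer."""
        spiked = sum(p.count_label(label) for p in self.retained)
        spiked += self.filtrate.count_label(label)
        captured = sum(p.count_label(label) for p in self.retained)
        return recovery_rate(captured, spiked)

    def summary(self) -> dict:
        layers = []
        for c, p in zip(self.cutoffs, self.retained):
            entry = {"cutoff_um": c, "count": len(p)}
            if len(p):
                entry["min_um"] = float(p.diameters.min())
                entry["max_um"] = float(p.diameters.max())
            layers.append(entry)
        return {
            "n_input": self.n_input,
            "layers": layers,
            "filtrate_count": len(self.filtrate),
        }


def passes(diameter: float, cutoff_dprime: float) -> bool:
    """Rigid-sphere sieve rule: pass iff diameter < d' (ties retained)."""
    if not diameter > 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    if not cutoff_dprime > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff_dprime}")
    return diameter < cutoff_dprime


def _pass_mask(
    diameters: np.ndarray,
    cutoff: float,
    softness: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    if softness == 0.0:
        return diameters < cutoff
    if rng is None:
        raise ValueError("softness > 0 requires an rng for probabilistic passage")
    # logistic pass probability, width softness·cutoff around the rigid rule
    p = 1.0 / (1.0 + np.exp((diameters - cutoff) / (softness * cutoff)))
    return rng.random(diameters.shape) < p


def filter_single(
    pop: ParticlePopulation,
    cutoff: float,
    softness: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FiltrationOutcome:
    """Sieve a population through one membrane of flat-to-flat cutoff (μm)."""
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if len(pop) == 0:
        warnings.warn("filtering an empty population", stacklevel=2)
        labelled = pop.labels is not None
        return FiltrationOutcome(
            [_empty_population(labelled)], _empty_population(labelled), [cutoff]
        )
    mask = _pass_mask(pop.diameters, cutoff, softness, rng)
    return FiltrationOutcome([pop.subset(~mask)], pop.subset(mask), [cutoff])


def filter_stack(
    pop: ParticlePopulation,
    stack: MembraneStack,
    softness: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FiltrationOutcome:
    """Sieve sequentially through a stack, top cutoff first."""
    retained: list[ParticlePopulation] = []
    current = pop
    for cutoff in stack.cutoffs:
        if len(current) == 0:
            labelled = pop.labels is not None
            retained.append(_empty_population(labelled))
            continue
        mask = _pass_mask(current.diameters, cutoff, softness, rng)
        retained.append(current.subset(~mask))
        current = current.subset(mask)
    return FiltrationOutcome(retained, current, list(stack.cutoffs))


def recovery_rate(retained_target: int, spiked: int) -> float:
    """Fraction of spiked target particles recovered, in [0, 1]."""
    if spiked <= 0:
        raise ValueError(f"spiked count must be positive, got {spiked}")
    if not 0 <= retained_target <= spiked:
        raise ValueError(
            f"retained count {retained_target} outside [0, {spiked}]"
        )
    return retained_target / spiked


def recovery_summary(counts: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """Mean and sd of recovery over replicate (retained, spiked) pairs."""
    rates = np.array([recovery_rate(r, s) for r, s in counts])
    return float(rates.mean()), float(rates.std(ddof=1)) if len(rates) > 1 else 0.0


def size_histogram(
    pop: ParticlePopulation, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of particle diameters with fixed bin width (μm).

    Returns (counts, bin_edges); counts sum to the population size.  Bin
    edges align to multiples of the bin width.
    """
    if not bin_width > 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    if len(pop) == 0:
        return np.empty(0, dtype=int), np.empty(0)
    lo = np.floor(pop.diameters.min() / bin_width) * bin_width
    hi = np.ceil(pop.diameters.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, edges = np.histogram(pop.diameters, bins=edges)
    return counts, edges
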