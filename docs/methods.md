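# Methods

`hexpore` models thin, large-area polymer membranes perforated by a
close-packed array of regular hexagonal micropores, the kind used for
gravity-driven, size-based separation of particles and rare cells (liquid
biopsy).  Four physical stages are covered: array design geometry, the
elastic response of the loaded membrane, the Stokes-regime hydraulics of the
pore array, and deterministic sieve fractionation of a particle population.
A seeded synthetic-data layer generates every input the pipeline consumes.

## Design geometry

A pore is a regular hexagon of diagonal (vertex-to-vertex) width *d*; its
flat-to-flat width is *d′ = d·√3/2*, which is the sieving-relevant aperture.
Pores sit on a hexagonal lattice with inter-pore wall width *s*, so the
center-to-center pitch is *d′ + s* and the tiling cell is the concentric
hexagon of flat-to-flat width *d′ + s*.  The open-area fraction is the
squared linear ratio

    φ = (d′ / (d′ + s))²,

the pore density is one pore per cell area (√3/2)(d′+s)², and the inverse
design *s(φ, d) = d′(1/√φ − 1)* is closed-form.  Porosity is always computed
from **design** values of *d* and *s*: these reproduce the published
six-case porosity column exactly at two decimal places, whereas measured
post-fabrication widths do not.  The pore cross-section is treated as a
perfect hexagonal prism (vertical sidewalls through the thickness), which
matches the steep sidewall profiles these membranes exhibit.

## Plate mechanics

The clamped membrane under load is described by large-deflection
(Timoshenko-type) circular-plate theory.  With equivalent Young's modulus
*E*, Poisson ratio *μ* (0.5 for Parylene C), thickness *h* and effective
clamped radius *a*, the center deflection *d_v* under a **concentrated**
center load *q_c* satisfies

    (353−191μ)/(648(1−μ)) · E h d_v³ + 4 E h³ d_v / (3(1−μ)) = q_c a²/π,

and under a **uniformly distributed** total load *q_u*

    (23−9μ)/(252(1−μ)) · E h d_v³ + 2 E h³ d_v / (9(1−μ)) = q_u a²/24.

Both loads are *total forces* (N): only that reading makes the two laws
dimensionally consistent as written (`E·h·d_v³ ~ N·m²`), and a helper
converts an average pressure over the loaded span into a total force.  The
membranes are square sheets; the effective radius defaults to half the
13 mm effective filtration span (a = 6.5 mm) and is configurable.

Both laws are strictly increasing depressed cubics in *d_v* for 0 < μ < 1,
so the forward solve has exactly one nonnegative root.  It is evaluated with
the hyperbolic closed form `x = 2√(p/3)·sinh(asinh(3q/(2p)·√(3/p))/3)`,
which is cancellation-free in both the bending-dominated (linear) and
stretching-dominated (cubic) limits; tests pin it against a bracketing
bisection to 10 significant digits.

**Modulus extraction.**  Both laws are linear in *E* (`q = E·f(d_v)` with
*f* the geometry factor), so the fit is closed form and deterministic.
Because the measured, noisy quantity is the deflection — the *regressor* —
the naive through-origin slope `Σfq/Σf²` is attenuation-biased
(errors-in-variables): multiplicative deflection noise of 5 % biases it by
up to ≈ 3 % when the cubic term dominates.  `hexpore` therefore uses the
inverse-regression slope

    Ê = Σ q_i² / Σ f_i q_i,

which cancels the attenuation at leading order, agrees exactly with the
naive slope on noiseless data, and retains the linear-scaling property
(loads × k ⇒ Ê × k).  Its standard error is model-based: residuals in
*f*-space divided by the sensitivity of *f* to a relative deflection
perturbation give the implied relative deflection errors; their sample
variance is propagated through the delta method.  This pools all points
into one variance estimate and is much more stable than a sandwich
estimator when the cubic term concentrates weight on the few largest
deflections.  In the package's recovery simulation (5 % noise, 20 points,
200 replicates) the estimate is unbiased to well within 1 % and ±2·stderr
intervals cover the generating modulus ≈ 96–98 % of the time.

**Elongation.**  The deflected membrane's half-span stretches from *a* to
√(a² + d_v²), so the relative in-plane elongation is

    δ = √(a² + d_v²)/a − 1 = (d_v/a)² / (1 + √(1 + (d_v/a)²)),

(the second form is the numerically stable one; δ → (d_v/a)²/2 for small
deflections).  A pore of diameter *d_p* widens by δ·d_p.  At the reported
operating point (d_v ≈ 0.49 mm on a 6.5 mm half-span) this gives
δ ≈ 0.28 % and a pore-size change of ≈ 35–41 nm on the largest (≈ 13–15 μm)
pores — both consistent with the published sub-0.28 % / <40 nm bounds.

## Hydraulics

The full finite-element flow field is replaced by an analytic Stokes-regime
network, a deliberate approximation: each hexagonal pore is mapped to the
equal-area circular pore (r_eq = √(A_hex/π), A_hex = (3√3/8)d²) and its
resistance taken as the Dagan orifice-plus-channel form

    R₁ = (μ_f / r_eq³)·(3 + 8h/(π·r_eq)),

whose first term is the Sampson entrance/exit loss (both ends, counted
once) and whose second is the finite-length Poiseuille channel.  Identical
pores act in parallel (membrane resistance R₁/n), pressure drop is linear
in throughput, gravity drive supplies ΔP = ρ·g·head, and the per-pore wall
shear uses the standard Poiseuille form τ_w = 4μQ/(πr³).  The gravity head
is a required user parameter; absolute throughput figures are **not**
reproduced (the experimental head is unknown) — only scalings (linearity in
head and 1/viscosity, series/parallel composition) and the ordering of
designs by porosity, which the model preserves by construction.

## Sieving

Polystyrene beads are rigid, so passage is a pure diameter threshold: a
particle passes a membrane iff its diameter is strictly smaller than the
flat-to-flat aperture *d′*; ties are retained (conservative sieve —
measurement resolution makes exact ties measure-zero anyway).  A stack with
strictly decreasing cutoffs fractionates a load into disjoint, ordered size
windows: layer *i* traps exactly the particles in [d′_i, d′_{i−1}), and
counts are conserved exactly at every stage.  Simulations of the published
experiments default to the *measured* flat-to-flat cutoffs
(12.57/9.71/7.90/6.50 μm for the four-case cascade); design values are
selectable.  Retained-fraction purity is 100 % by construction (no
non-specific wall adhesion is modelled, matching observation).  Live cells
deform, so a logistic "softness" pass-probability is available, but it is
OFF by default and makes no claim to model the physical capture losses
behind sub-100 % cell recovery.

## Synthetic data

All generators take an explicit seed and are fully deterministic given it.

* **Load-deflection series** — deflections solve the concentrated-load
  cubic exactly at a known modulus, then each is multiplied by
  (1 + N(0, σ_rel)); σ_rel defaults to 5 %.  The default schedule places 20
  noiseless deflections uniformly over 0.1h–1.0h: up to about one membrane
  thickness, a realistic non-destructive test range that still exercises
  both the bending and the stretching term.
* **Bead mixtures** — monodispersed 9 μm and 12 μm standards as truncated
  normals with 2 % CV (vendor-typical for monosized standards; an assumed
  value), at the experimental loading of 243 000 + 87 000 = 330 000 beads;
  the multi-dispersed load is uniform over 6–22 μm (its real composition is
  unpublished; the choice affects per-layer counts, never the partition
  windows).  Truncation is enforced by rejection sampling, capped at 1000
  sweeps before signalling an impossible window.
* **T24 cell sizes** — truncated normal, mean 13.5 μm, sd 0.84 μm, support
  [8, 20] μm.

What the generators deliberately do **not** emulate: cell deformability,
background-cell interference in urine, clogging/fouling dynamics, and
measurement artifacts of flow-cytometry sizing.  Passing sieve tests
therefore demonstrate the correctness of the cutoff logic and the mechanics
of the pipeline, not the biological recovery rates.

## Problem sizes and numerical choices

Default test problem sizes: the porosity Monte-Carlo oracle uses 10⁶ points
per design (3σ agreement band), the solver cross-check uses 50 log-spaced
loads × 4 parameter sets at 10-significant-digit tolerance, parameter
recovery uses 200 replicates of 20-point series, and the multi-layer
sieving emulation uses a 5×10⁵-bead load (the single-layer one uses the
full 3.3×10⁵ experimental count).  Degenerate inputs (zero load, zero
deflection, empty populations, all-zero series) return exact zeros or raise
typed errors as documented per function; monotonicity violations in
measured series and non-decreasing stacks warn rather than fail, since both
remain computable.

## Known limitations

* The uniform-load law is implemented exactly as published (RHS divisor 24
  with a² — not the classical clamped-plate coefficient); the package
  follows the published form rather than "correcting" it.
* The equal-area circular-pore hydraulic model ignores the hexagonal
  cross-section's excess drag (a few percent) and any pore-pore
  interaction; it is a trend model, not a replacement for CFD.
* Equivalent-modulus values of porous membranes are design-dependent in
  reality (annealing, porosity); the package accepts any *E* but does not
  model its microstructural origin.
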