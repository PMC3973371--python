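# Methods

This note documents the models implemented in `frictionpad`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices that affect results.

## Contact model (`padmech`)

The pad is a **rigid spherical-cap envelope** over a bed of independent
elastic fibrils pressed against an ideally smooth rigid plane — a
Greenwood–Williamson-style asperity model in which the effective height
distribution is the sum of the dome sag `ρ²/(2R)` (parabolic cap
approximation) and per-fibril tip offsets drawn from a normal distribution
truncated at zero. Elastic deformation of the pad backing is omitted:
projected-area growth is attributed to pad curvature alone, density growth
to the tip-height spread. Fibril tilt at the pad periphery — a second
plausible density mechanism — is not modelled.

Each fibril follows a piecewise-linear constitutive law in vertical
overlap δ:

* **tip mode** (0 < δ ≤ δ_c): force `k·δ` with axial stiffness `k`;
  circular patch growing linearly from a minimum tip area (0.12 μm², the
  smallest optically resolvable contact) to the full spherical tip cap
  `π r_t²`.
* **side mode** (δ > δ_c): tangent stiffness reduced to `0.3·k` (the
  bending-dominated regime is softer than axial compression; no
  constitutive law is available, so the ratio is a configurable modelling
  choice); the elliptical patch's length and width grow linearly in
  (δ − δ_c) at rates chosen so that the patch reaches its area ceiling
  (4 μm², ≈17× the tip cap) exactly when the aspect ratio reaches 4.5,
  after `side_saturation_overlap` of post-critical travel. Aspect ratio
  therefore rises continuously from 1 to 4.5.

Force and area are continuous at the tip→side transition; there is no
Euler-buckling instability — the conical, low-slenderness geometry
(length/diameter ≈ 5, enforced at bed construction) is taken to deform
smoothly, consistent with the continuous aspect-ratio–area relationship
seen in contact images.

Shear load enters as a dimensionless **shear bias** that lowers the
effective critical overlap (sheared fibrils fall over into side contact
earlier) and aligns side-patch orientations with the shear direction;
`apply_shear` re-solves the normal-force balance under the bias, so real
contact area and the side-contact count are non-decreasing in shear, and
reversing the direction flips orientations by π without changing areas.

**Solver.** Total fibril force is continuous and non-decreasing in dome
descent, so the normal-force balance is solved by bracketing bisection to a
residual below `max(10⁻⁶·F_N, 10⁻³ nN)`. Fibrils within 10⁻¹² μm of the
contact boundary count as contacting. Projected area is the convex hull of
the contacting patches (each patch contributes its four axis endpoints),
capped at the pad footprint; density is the contacting count divided by
that hull; the decomposition `A_R = A_A·N_A·A_Ac` then holds as an exact
identity. The model is purely elastic: load sweeps are reversible with no
hysteresis. If a load cannot be balanced within an allowed descent (only
possible with zero side stiffness), the state at capacity is returned with
a `saturated` flag and a warning.

**Units.** Internally μm / nN / kPa (1 nN/μm² = 1 kPa); observation tables
report mm² (projected area), μm⁻² (density), μm² (per-fibril and real
area), mN (force), MPa (stress). All conversion constants live in
`padmech`.

### Calibrated defaults

Free parameters without direct measurements were calibrated **once**
against the emergent behaviour required of the default pad (all three
log–log slopes strictly inside (0, 1); ≥10× real-area growth over
0.2–4 mN; projected area at 4 mN below the 0.1 mm² footprint ceiling;
projected area roughly tripling) and then frozen:

| parameter | default | rationale |
| --- | --- | --- |
| footprint area | 1.0×10⁵ μm² | pad-pair surface-area ceiling (0.1 mm²) |
| areal density | 0.19 μm⁻² | SEM density ceiling |
| dome radius `R` | 4000 μm | sets projected-area growth and its saturation near 4 mN |
| tip-height sd | 2.5 μm | truncated-normal spread; sets density growth |
| axial stiffness `k` | 500 nN/μm | sets the load→descent scale over the 0.2–4 mN sweep |
| critical overlap δ_c | 1.2 μm | tip→side transition (asserted but unquantified in observations) |
| side saturation travel | 10 μm | full side contact within the 12 μm fibril length |
| side/axial stiffness ratio | 0.3 | bending softer than compression |
| tip radius `r_t` | 0.27 μm | tip cap π r_t² ≈ 0.23 μm², tip-only contact scale; tip coverage 0.19·π r_t² ≈ 4.4% < 5% |

With these defaults the simulated sweep gives slopes ≈ 0.39 / 0.30 / 0.20
(projected area / density / per-fibril area, sum ≈ 0.89) and a 14.6× real
contact-area increase — the same qualitative regime as the measured pads
(0.362 / 0.214 / 0.226, sum 0.802, ~10.8×), without any exponent being
imposed.

## Synthetic data (`synthgen`)

* **Placement**: jittered hexagonal lattice (default) — the maximum-density
  packing consistent with the 0.19 μm⁻² ceiling, avoiding unphysical
  overlaps; uniform-random placement is available. Counts are trimmed to
  `round(density × area)`, so realised density errs only by footprint
  discretisation.
* **Populations**: per-individual multiplicative (log-normal) factors on
  tip-height spread, stiffness and dome radius with log-sd
  `individual_jitter` (default 0.10), matching the multiplicative
  random-intercept structure assumed by the log–log mixed model. Factors
  are returned as ground truth.
* **Images**: patches are rendered as filled ellipses via 4× supersampled
  coverage plus a ~2 px Gaussian edge blur, bright (0.85) on dark (0.12),
  optional Gaussian intensity noise; 16-bit TIFF with a JSON pixel-scale
  sidecar. The default pixel scale of 0.05 μm/px puts ≈3 px per optical
  resolution element and resolves the smallest reported contact
  (0.12 μm²). Optics (interference, numerical aperture, secretion
  droplets) are **not** modelled: passing round-trip tests shows the
  measurement chain is unbiased on ideal ellipse images, not that it is
  robust to real microscope artefacts.
* **Friction**: `F_F = τ·A_R + ε` with τ = 1 MPa (the measured constant
  shear stress) and Gaussian noise of sd 0.3 mN — a per-observation
  force-transducer-scale error chosen to reproduce a median ± MAD spread
  of the recovered shear stress comparable to the reported 1.00 ± 0.49 MPa.
* **Power-law benchmark tables**: `y = a·F^k·10^(b_i + ε)` with b_i, ε on
  the log₁₀ scale. Default exponents (0.362, 0.214, 0.226) and 1 mN
  prefactors (0.080 mm², 0.107 μm⁻², 0.326 μm²) are the published
  estimates; default variance components (individual sd 0.12, residual sd
  0.03 log₁₀ units) were back-computed from the published conditional
  (≈0.97) and marginal (≈0.65) R² of the projected-area fit.

Every generator is a pure function of its seed (numpy `default_rng` /
`SeedSequence`); the pipeline derives per-stage child seeds from the global
seed via `SeedSequence([seed, stage_index])`.

## Image quantification (`imquant`)

Segmentation is Otsu by default (fixed threshold optional), idempotent on
binary input; constant images yield an empty mask with a warning. Particle
metrics come from connected components (8-connectivity default, the common
particle-analysis convention; 4-connectivity available) with axes and
orientation from the moment-equivalent ellipse; spots under 9 px are
flagged `unreliable_aspect` rather than dropped, since moment ellipses are
meaningless at a few pixels. "Smallest polygon containing all contacts" is
interpreted as the **convex hull** (the manual protocol it mirrors could in
principle draw a concave polygon; concavity is not implemented and hull
areas are therefore upper bounds). Density uses square windows
rejection-sampled fully inside the hull until they cover the requested
fraction of its area (default 0.25, the fraction sampled by the original
protocol; windows may overlap); `sample_fraction=1` short-circuits to exact
count/hull-area. The optical boundary-error model is
`perimeter·(resolution/2)/area` with the area-equivalent-circle perimeter
by default (`resolution` = 0.15 μm, the ±150 nm microscope limit), which
reproduces the ≈75% error of the smallest 0.12 μm² contacts; passing the
true perimeter gives a strictly larger error for elongated spots.

## Statistics (`scalestats`)

The random-intercept model `log₁₀ y = β₀ + β₁ log₁₀ F + b_i + ε` is fitted
by REML, profiled over the variance ratio λ = σ²_between/σ²_residual and
optimised by bounded scalar search on log λ ∈ [−30, 30]; block-diagonal
group structure is solved by the Woodbury identity. The implementation
agrees with `statsmodels` MixedLM to ≥4 decimals in the tests (kept as an
independent cross-check, not a dependency). Marginal and conditional R²
follow the Nakagawa–Schielzeth variance decomposition. Degenerate cases:
an exactly line-on-line dataset returns a closed-form fit with conditional
R² = 1; a boundary estimate λ → 0 (no detectable between-individual
variance) falls back to pooled OLS with a logged note. Log base 10 is used
throughout; intercepts are reported in log₁₀ of the table units (mm²,
μm⁻², μm² versus mN), so they are convention-dependent and only slopes
and R² should be compared across conventions.

Friedman's test uses within-row mid-ranks with the standard tie
correction and the asymptotic χ² distribution (k−1 df); a fully tied
matrix returns χ² = 0, p = 1. The repeated-measures ANCOVA effect size is
η² = SS_load/SS_total with individuals as the blocking factor (Type I,
load after blocks; df matching the 10 × 5 design: F₁,₃₉); its confidence
interval is a seeded percentile bootstrap over individuals (2000
resamples) — chosen because the original noncentrality-based CI procedure
is not specified in enough detail to reimplement exactly. Summary
conventions: mean ± t-based margin (half the 95% CI), and median ± **raw**
MAD (no 1.4826 normal-consistency factor, matching the reporting
convention being emulated).

## Friction laws (`frictionlaws`)

The extended-Amonton fit is OLS of **per-load median** friction on load
(as in the analysis it reproduces), with `F_A = F_0/μ`, undefined when
μ ≤ 0. Shear stress is `τ = F_F/A_R` per observation (mN/μm² → MPa), with
constancy assessed by the Friedman test across loads and summarised as
median ± MAD. `μ = τ·C` with C the OLS slope of A_R (mm²) on load (mN);
note that C computed from composed group means (≈1.4×10⁻³ mm²/mN) differs
from the individual-data value (≈2.1×10⁻³) — only the order of magnitude
(10³ × steel) is meaningful from the means. JKR contact uses
`a³ = (R/K)(F + 3πWR + √(6πWRF + (3πWR)²))` with pull-off `(3/2)πWR`; the
printed "1 MPa stiffness" of the comparison sphere is treated as the
effective modulus E\* (Poisson effects unspecified), K = 4E\*/3. The
0.33 MPa acantha adhesion-per-area example back-solves a 0.2 μm² circular
tip area from the 66 nN single-hair adhesion estimate; the underlying tip
radius is not independently available, so it is a consistency check only.
The material-comparison curves use the fitted power law for the pad (not
raw means), a linear `C·F` line for steel, and the JKR sphere.

## Problem sizes

The default study design is 10 individuals × 5 loads on full-density beds
(19 000 fibrils); a full simulate→render→quantify→fit→friction run takes a
few seconds on one CPU. Brute-force oracles (fine-grid descent scans,
rank enumerations) run on ≤20-fibril beds and 4×3 matrices; image
round-trip tests use ~250-spot scenes at 0.05 μm/px.

## Known limitations

* No dynamic sliding, stick-slip, viscoelasticity, secretion-fluid
  mechanics or substrate roughness (the reference substrate is ideally
  smooth glass).
* Only the height-spread mechanism of density growth is implemented;
  peripheral fibril tilt is noted as an extension.
* The tip→side critical overlap and the side-contact growth law are
  modelling choices validated by emergent power-law behaviour, not by
  direct per-fibril measurements.
* Rendered images idealise the optics; quantification accuracy on real
  micrographs will be worse than the round-trip tolerances suggest.
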