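# frictionpad

Contact mechanics, image quantification and friction-law analysis of
**fibrillar insect friction pads** — the "heel pads" (euplantulae) of stick
insects, which are covered by arrays of micrometre-scale conical hairs
(acanthae), generate large friction coefficients under load, yet adhere
almost not at all.

The package is aimed at attachment-biomechanics and bio-inspired-surface
researchers who want a fully testable, download-free reimplementation of
this analysis: a mechanistic simulator of the fibril bed stands in for the
insect, a renderer stands in for the microscope, and every statistical step
runs on data with known ground truth.

## The model

Real contact area of the pad decomposes hierarchically into three levels
that each respond to normal load `F_N`:

```
A_R = A_A · N_A · A_Ac
```

* `A_A` — projected contact area (smallest convex polygon around all
  contacting hairs), mm²;
* `N_A` — areal density of hairs in contact, μm⁻²;
* `A_Ac` — mean contact area of a single hair, μm² (circular *tip* contact
  → elongated *side* contact as hairs bend, aspect ratio 1 → 4.5).

Each level follows an empirical power law `y ∝ F_N^k` with `0 < k < 1`,
fitted on log₁₀–log₁₀ data with a random intercept per individual
(repeated-measures design; marginal and conditional R² reported).
Multiplying the three laws gives

```
A_R ∝ F_N^(k_AA + k_NA + k_AAc),   with k_AA + k_NA + k_AAc = 0.802
```

for the published per-level coefficients — a near-linear growth of real
contact area with load. With friction proportional to real contact area
through a constant interfacial shear stress τ (`F_F = τ·A_R ≈ 1 MPa · A_R`),
this explains load-dependent friction coefficients `μ_app = τ·a·F_N^(k−1)`
that exceed 1 at small loads: the pad behaves like a rigid solid at zero
load (negligible contact, negligible adhesion) but like a soft material
under load (rapid contact-area growth). The package also implements the
comparison cases: the adhesion-extended Amonton law `F_F = μ(F_N + F_A)`,
the rigid-solid law `μ = τ·C`, and JKR adhesive-sphere contact.

The simulator (`padmech`) realises the mechanism behind each level: a rigid
convex dome (pad curvature → `A_A` growth) carrying elastic conical fibrils
with non-coplanar tips (height distribution → `N_A` growth) that switch
smoothly from tip to side contact past a critical overlap (→ `A_Ac`
growth). All three exponents *emerge* from the geometry; none is imposed.

## Worked example

```python
>>> import frictionpad as fp
>>> # three-level composition of the published 4 mN group means
>>> fp.real_contact_area(0.101, 0.132, 0.461)   # mm², μm⁻², μm² -> μm²
6146.052000000001
>>> fp.real_contact_area(0.101, 0.132, 0.461) / fp.real_contact_area(0.034, 0.071, 0.235)
10.834056655326203
>>> # adhesion-equivalent load from the friction-load regression line
>>> fit = fp.fit_amonton_extended([1, 2, 4], [1.25*F + 2.42 for F in [1, 2, 4]])
>>> fit.mu, fit.F0, fit.F_adh
(1.25, 2.4199999999999986, 1.9359999999999988)
>>> # rigid-solid arithmetic: steel on steel
>>> fp.rigid_mu(800.0, 1e-6)     # tau [MPa] x C [mm²/mN] -> mu
0.7999999999999999
```

Real contact area grows ~10.8× (an order of magnitude) across the 0.2–4 mN
load range while projected area only triples; the friction line's intercept
implies an adhesion-equivalent load F_A = F_0/μ ≈ 1.94 mN even though the
pads show almost no measurable adhesion — the motivation for the
contact-area-growth explanation of friction.

An end-to-end simulated study (10 individuals × 5 loads, images, fits,
friction laws) runs from the shell:

```sh
frictionpad run-all --seed 42 --out runs/demo
```

which writes `observations.csv`, a rendered `contact_image.tif` (+ JSON
pixel-scale sidecar), particle and summary tables, `load_summary.csv`
(mean ± t-based margin per load), `powerlaw_fits.csv` (slope ± SE with
conditional/marginal R² per level), `friction_fit.csv` (μ, F_0, F_A, τ
median ± MAD, growth rate C) and `material_curves.csv` (pad vs steel vs
JKR sphere), plus full run metadata.

## Layout

| module | contents |
| --- | --- |
| `frictionpad.synthgen` | fibril beds, populations, contact-image rendering, friction traces, power-law benchmark tables |
| `frictionpad.padmech` | fibril tip/side response, indentation solver, shear re-solve, load sweeps |
| `frictionpad.imquant` | segmentation, particle analysis, convex-hull projected area, density windows, optical boundary error |
| `frictionpad.scalestats` | A_R decomposition, random-intercept power-law fits, Friedman test, η², summary conventions |
| `frictionpad.frictionlaws` | Amonton fits, shear stress, apparent/rigid μ, JKR contact, material curves |
| `frictionpad.pipeline` / `cli` | YAML-configured stage orchestration, validation, `frictionpad` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
their rationale, and known limitations.
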