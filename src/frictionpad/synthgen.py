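"""Synthetic ground-truth generators for the friction-pad pipeline.

Everything downstream (image quantification, scaling statistics, friction
laws) is testable against data produced here with known ground truth:

* fibril beds with controlled areal density and tip-height spread under a
  curved pad envelope,
* populations of individuals with multiplicative (log-normal) parameter
  variation, emulating a repeated-measures study design of 10 individuals
  observed at 5 normal loads (0.2, 0.5, 1, 2, 4 mN),
* rendered contact images (bright elliptical patches on a dark background)
  with known per-patch area, aspect ratio and orientation,
* friction traces obeying a constant shear stress F_F = τ·A_R plus Gaussian
  noise (τ defaults to 1 MPa),
* tabular power-law benchmark datasets with known exponents, per-individual
  offsets and residual noise on the log10 scale.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imquant import ContactImage
from .padmech import (
    KPA_PER_MPA,
    MAX_DENSITY,
    NN_PER_MN,
    UM2_PER_MM2,
    ContactState,
    FibrilBed,
    PadGeometry,
)

#: Default pixel scale of rendered images, μm/px — about 3 px per optical
#: resolution element, resolving the smallest reported contact (0.12 μm²).
DEFAULT_PIXEL_SCALE = 0.05

#: Default study design: normal loads in mN and number of individuals.
STUDY_LOADS = (0.2, 0.5, 1.0, 2.0, 4.0)
STUDY_N_INDIVIDUALS = 10

#: Published-estimate generating exponents of the three contact-area responses
#: over load, and their prefactors at 1 mN (mm², μm⁻², μm²).
DEFAULT_EXPONENTS = (0.362, 0.214, 0.226)
DEFAULT_PREFACTORS = (0.080, 0.107, 0.326)


@dataclass
class SynthParams:
    """Shared parameters of the synthetic study design.

    ``individual_jitter`` is the log-scale (natural-log) s.d. of the
    multiplicative factors applied to per-individual bed parameters;
    ``tip_height_sd`` is the s.d. of the underlying normal whose
    truncation-at-zero gives the tip-height offsets (μm).
    """

    n_individuals: int = STUDY_N_INDIVIDUALS
    loads: tuple[float, ...] = STUDY_LOADS
    tip_height_sd: float = 2.5
    density: float = MAX_DENSITY
    tau_true: float = 1.0  # MPa
    friction_noise_sd: float = 0.3  # mN
    individual_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        loads = tuple(float(l) for l in self.loads)
        if len(loads) == 0 or any(l <= 0 for l in loads):
            raise ValueError("loads must be non-empty and strictly positive")
        if list(loads) != sorted(loads):
            raise ValueError("loads must be sorted ascending")
        self.loads = loads
        for name in ("tip_height_sd", "friction_noise_sd", "individual_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.density <= MAX_DENSITY:
            raise ValueError(f"density must lie in (0, {MAX_DENSITY}] μm⁻²")


# ---------------------------------------------------------------------------
# fibril bed generation
# ---------------------------------------------------------------------------
def make_fibril_bed(
    density: float,
    pad: PadGeometry,
    tip_height_sd: float,
    seed: int = 0,
    placement: str = "hex",
    jitter_frac: float = 0.2,
    **bed_kwargs,
) -> FibrilBed:
    """Place fibrils at a given areal density under a pad envelope.

    ``placement='hex'`` (default) uses a jittered hexagonal lattice — the
    maximum-density packing consistent with the 0.19 μm⁻² ceiling and free
    of unphysical overlaps; ``placement='uniform'`` draws fully random
    positions.  The realised count is trimmed/padded to match
    ``round(density × footprint_area)`` exactly, so the density error is
    pure footprint discretisation (≪2%).

    Tip offsets (height below the local envelope) are drawn from a normal
    distribution truncated at zero with underlying s.d. ``tip_height_sd``;
    ``tip_height_sd=0`` gives a coplanar bed.
    """
    if not 0 < density <= MAX_DENSITY:
        raise ValueError(
            f"density {density} μm⁻² is super-physical (ceiling {MAX_DENSITY})")
    if tip_height_sd < 0:
        raise ValueError("tip_height_sd must be >= 0")
    rng = np.random.default_rng(seed)
    R = pad.footprint_radius
    target = int(round(density * pad.footprint_area))
    if target < 1:
        raise ValueError("footprint too small for the requested density")

    if placement == "hex":
        s = float(np.sqrt(2.0 / (np.sqrt(3.0) * density)))  # lattice constant
        ny = int(np.ceil(2 * R / (s * np.sqrt(3) / 2))) + 2
        nx = int(np.ceil(2 * R / s)) + 2
        jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        x = (ii + 0.5 * (jj % 2)) * s - R
        y = jj * s * np.sqrt(3) / 2 - R
        pts = np.column_stack([x.ravel(), y.ravel()])
        pts += rng.uniform(-jitter_frac * s, jitter_frac * s, pts.shape)
    elif placement == "uniform":
        # oversample the bounding square, keep the disc
        n_try = int(np.ceil(target * 4 / np.pi * 1.2)) + 16
        pts = rng.uniform(-R, R, (n_try, 2))
    else:
        raise ValueError(f"unknown placement {placement!r}")

    pts = pts + np.asarray(pad.apex)
    inside = np.sum((pts - np.asarray(pad.apex)) ** 2, axis=1) <= R**2
    pts = pts[inside]
    if len(pts) > target:
        keep = rng.choice(len(pts), size=target, replace=False)
        pts = pts[np.sort(keep)]
    while len(pts) < target:  # rare boundary shortfall
        extra = rng.uniform(-R, R, (target - len(pts), 2)) + np.asarray(pad.apex)
        ok = np.sum((extra - np.asarray(pad.apex)) ** 2, axis=1) <= R**2
        pts = np.vstack([pts, extra[ok]])

    offsets = np.abs(rng.normal(0.0, tip_height_sd, len(pts))) \
        if tip_height_sd > 0 else np.zeros(len(pts))
    return FibrilBed(positions=pts, tip_offsets=offsets,
                     footprint_area=pad.footprint_area, **bed_kwargs)


# ---------------------------------------------------------------------------
# populations with repeated-measures structure
# ---------------------------------------------------------------------------
def make_population(
    params: SynthParams,
    pad: PadGeometry | None = None,
) -> tuple[list[tuple[FibrilBed, PadGeometry]], pd.DataFrame]:
    """Generate one bed+pad per individual with log-normal parameter jitter.

    Multiplicative factors ``exp(N(0, individual_jitter))`` are applied
    per individual to tip-height spread, axial stiffness and dome radius
    (density stays at the shared value, capped by the physical ceiling).
    The per-individual factors are returned as ground truth for
    mixed-model variance-recovery tests.
    """
    base_pad = pad or PadGeometry()
    ss = np.random.SeedSequence(params.seed)
    bed_seeds = ss.spawn(params.n_individuals)
    rng = np.random.default_rng(ss.spawn(1)[0])

    items: list[tuple[FibrilBed, PadGeometry]] = []
    records = []
    for i in range(params.n_individuals):
        f_sd, f_k, f_R = (
            np.exp(rng.normal(0.0, params.individual_jitter, 3))
            if params.individual_jitter > 0 else np.ones(3))
        ipad = replace(base_pad, dome_radius=base_pad.dome_radius * f_R)
        bed = make_fibril_bed(
            density=params.density,
            pad=ipad,
            tip_height_sd=params.tip_height_sd * f_sd,
            seed=bed_seeds[i].generate_state(1)[0] % (2**31),
        )
        bed = replace(bed, axial_stiffness=bed.axial_stiffness * f_k)
        items.append((bed, ipad))
        records.append({
            "individual_id": f"ind{i:02d}",
            "tip_height_sd_factor": float(f_sd),
            "stiffness_factor": float(f_k),
            "dome_radius_factor": float(f_R),
        })
    return items, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# contact-image rendering
# ---------------------------------------------------------------------------
def render_patches(
    centers: np.ndarray,
    areas: np.ndarray,
    aspects: np.ndarray,
    orientations: np.ndarray,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    noise_sd: float = 0.0,
    seed: int = 0,
    region: tuple[float, float, float, float] | None = None,
    supersample: int = 4,
    edge_blur_px: float = 0.85,
    fg: float = 0.85,
    bg: float = 0.12,
) -> ContactImage:
    """Render elliptical contact patches into a grayscale image.

    Each patch is a filled ellipse of the given area, aspect ratio
    (major/minor) and orientation, anti-aliased by supersampled coverage
    and softened by a Gaussian edge blur (~2 px kernel); optional Gaussian
    intensity noise on top.  ``region`` is (x0, y0, x1, y1) in μm; by
    default the patch bounding box plus a 2 μm margin.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    areas = np.asarray(areas, dtype=float).ravel()
    aspects = np.asarray(aspects, dtype=float).ravel()
    orientations = np.asarray(orientations, dtype=float).ravel()
    n = len(areas)
    meta: dict = {"seed": seed, "n_patches": n, "warnings": []}

    if region is None:
        if n:
            r_max = float(np.sqrt(areas.max() * aspects.max() / np.pi)) + 1.0
            x0, y0 = centers.min(axis=0) - r_max - 1.0
            x1, y1 = centers.max(axis=0) + r_max + 1.0
            region = (x0, y0, x1, y1)
        else:
            region = (0.0, 0.0, 10.0, 10.0)
    x0, y0, x1, y1 = region
    W = max(int(np.ceil((x1 - x0) / pixel_scale)), 1)
    H = max(int(np.ceil((y1 - y0) / pixel_scale)), 1)

    if n and areas.min() / pixel_scale**2 < 4:
        msg = ("smallest patch covers <4 px at this pixel scale; "
               "measurements will be unreliable")
        warnings.warn(msg, stacklevel=2)
        meta["warnings"].append(msg)

    ss = supersample
    cover = np.zeros((H * ss, W * ss), dtype=float)
    scale_ss = pixel_scale / ss
    for (cx, cy), area, asp, th in zip(centers, areas, aspects, orientations):
        if area <= 0:
            continue
        b = np.sqrt(area / (np.pi * asp))  # minor semi-axis, μm
        a = asp * b
        # bounding box in supersampled pixels
        r = a
        j0 = max(int((cx - r - x0) / scale_ss) - 1, 0)
        j1 = min(int((cx + r - x0) / scale_ss) + 2, W * ss)
        i0 = max(int((cy - r - y0) / scale_ss) - 1, 0)
        i1 = min(int((cy + r - y0) / scale_ss) + 2, H * ss)
        if j1 <= j0 or i1 <= i0:
            continue
        xs = x0 + (np.arange(j0, j1) + 0.5) * scale_ss
        ys = y0 + (np.arange(i0, i1) + 0.5) * scale_ss
        dx = xs[None, :] - cx
        dy = ys[:, None] - cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        cover[i0:i1, j0:j1] = np.maximum(
            cover[i0:i1, j0:j1], ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float))

    cover = cover.reshape(H, ss, W, ss).mean(axis=(1, 3))
    if edge_blur_px > 0:
        cover = gaussian_filter(cover, edge_blur_px)
    img = bg + (fg - bg) * cover
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    meta.update(region_um=list(region), fg=fg, bg=bg, noise_sd=noise_sd)
    return ContactImage(pixels=img, pixel_scale=pixel_scale, metadata=meta)


def render_contact_image(
    state: ContactState,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    noise_sd: float = 0.0,
    seed: int = 0,
    region: tuple[float, float, float, float] | None = None,
    **kwargs,
) -> ContactImage:
    """Render the contacting patches of a solved contact state.

    Patch area, aspect ratio and orientation are taken directly from the
    state, so image-quantification round trips have exact ground truth.
    """
    m = state.contacting
    return render_patches(
        centers=state.bed.positions[m],
        areas=state.contact_area[m],
        aspects=state.aspect_ratio[m],
        orientations=state.orientation[m],
        pixel_scale=pixel_scale, noise_sd=noise_sd, seed=seed,
        region=region, **kwargs)


# ---------------------------------------------------------------------------
# friction traces
# ---------------------------------------------------------------------------
def synth_friction(
    a_r_series: np.ndarray | Sequence[float],
    tau: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Friction forces (mN) from real contact areas (μm²) at constant shear
    stress ``tau`` (MPa) plus Gaussian noise.

    1 MPa × 1 μm² = 10³ nN = 10⁻³ mN, so ``F_F = tau · A_R · 1e-3`` mN.
    """
    a_r = np.asarray(a_r_series, dtype=float)
    if np.any(a_r < 0):
        raise ValueError("A_R must be >= 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    friction = tau * KPA_PER_MPA * a_r / NN_PER_MN
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        friction = friction + rng.normal(0.0, noise_sd, a_r.shape)
    return friction


# ---------------------------------------------------------------------------
# power-law benchmark datasets
# ---------------------------------------------------------------------------
def make_powerlaw_dataset(
    exponents: Sequence[float] = DEFAULT_EXPONENTS,
    prefactors: Sequence[float] = DEFAULT_PREFACTORS,
    individual_sd: float = 0.12,
    noise_sd: float = 0.03,
    params: SynthParams | None = None,
    with_friction: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Observation table with known power-law ground truth.

    Each response column is generated per individual i and load F as

        y = prefactor · F^k · 10^(b_i + ε),   b_i ~ N(0, individual_sd),
                                              ε  ~ N(0, noise_sd),

    with offsets and noise on the log10 scale (multiplicative per-individual
    variation, matching the log–log mixed model downstream).  A_R is
    composed via A_R = A_A·N_A·A_Ac and, optionally, a friction column is
    added at the constant shear stress ``params.tau_true``.

    Returns the table and a ground-truth dict (exponents, prefactors,
    per-individual log10 offsets, noise level).
    """
    params = params or SynthParams()
    exponents = tuple(float(k) for k in exponents)
    prefactors = tuple(float(a) for a in prefactors)
    if len(exponents) != 3 or len(prefactors) != 3:
        raise ValueError("need exactly three exponents and prefactors "
                         "(A_A, N_A, A_Ac)")
    if individual_sd < 0 or noise_sd < 0:
        raise ValueError("sds must be >= 0")
    if not np.all(np.isfinite(exponents)):
        raise ValueError("exponents must be finite")

    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    loads = np.asarray(params.loads)
    n_i, n_l = params.n_individuals, len(loads)
    cols = ("A_A_mm2", "N_A_per_um2", "A_Ac_um2")

    offsets = (rng.normal(0.0, individual_sd, (n_i, 3))
               if individual_sd > 0 else np.zeros((n_i, 3)))
    rows = []
    for i in range(n_i):
        for load in loads:
            rec = {"individual_id": f"ind{i:02d}", "load_mN": float(load)}
            for j, (col, k, a) in enumerate(zip(cols, exponents, prefactors)):
                eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rec[col] = a * load**k * 10.0 ** (offsets[i, j] + eps)
            rec["A_R_um2"] = (rec["A_A_mm2"] * UM2_PER_MM2
                              * rec["N_A_per_um2"] * rec["A_Ac_um2"])
            rows.append(rec)
    df = pd.DataFrame(rows)
    if with_friction:
        df["friction_mN"] = synth_friction(
            df["A_R_um2"].to_numpy(), tau=params.tau_true,
            noise_sd=params.friction_noise_sd,
            seed=int(ss.spawn(2)[1].generate_state(1)[0] % (2**31)))
    truth = {
        "exponents": dict(zip(cols, exponents)),
        "prefactors": dict(zip(cols, prefactors)),
        "individual_log10_offsets": offsets,
        "individual_sd": individual_sd,
        "noise_sd": noise_sd,
        "tau_true": params.tau_true,
    }
    return df, truth
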