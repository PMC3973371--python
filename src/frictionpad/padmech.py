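"""Forward contact mechanics of a fibrillar friction pad.

The pad is modelled as a rigid convex dome (spherical-cap envelope) carrying a
bed of short conical fibrils (acanthae) that act as independent elastic
elements against an ideally smooth, rigid, flat substrate — a
Greenwood–Williamson-style rough-contact picture in which the "asperity"
height distribution is the distribution of fibril tip heights below the pad
envelope, plus the geometric sag of the dome itself.

Each fibril responds to vertical overlap with a piecewise-linear law:

* ``tip`` regime (overlap below a critical value): axial compression of the
  conical shaft, circular contact patch growing from a minimum tip area to the
  full spherical tip cap, aspect ratio 1.
* ``side`` regime (overlap beyond critical): the fibril bends over and its
  flank rolls into contact; the patch elongates continuously (aspect ratio
  growing from 1 towards 4.5), area saturating at the full side-contact
  maximum, with a reduced tangent stiffness relative to axial compression.

Force and contact area are continuous through the tip-to-side transition;
there is no buckling instability — the conical, low-aspect-ratio geometry is
taken to deform smoothly.

Internal units are μm (length), nN (force) and therefore nN/μm² = kPa
(stress).  Public observation tables convert to the conventional reporting
units mm² (projected area), μm⁻² (density), μm² (per-fibril area) and mN
(force); 1 MPa = 10³ kPa = 10³ nN/μm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

# ---------------------------------------------------------------------------
# unit conversions (single source of truth for the package)
# ---------------------------------------------------------------------------
UM2_PER_MM2 = 1.0e6  #: μm² in one mm²
NN_PER_MN = 1.0e6  #: nN in one mN
KPA_PER_MPA = 1.0e3  #: kPa (= nN/μm²) in one MPa

#: SEM-derived ceiling on areal fibril density, μm⁻².
MAX_DENSITY = 0.19
#: Default surface-area ceiling of a pad pair, μm² (0.1 mm²).
DEFAULT_FOOTPRINT_AREA = 1.0e5
#: Maximum aspect ratio of a full side contact.
ASPECT_MAX = 4.5
#: Smallest resolvable circular tip contact, μm².
TIP_AREA_MIN = 0.12
#: Full side-contact area ceiling, μm² (≈20× a tip-only contact).
SIDE_AREA_MAX = 4.0

#: Target slenderness (length / basal diameter) of a conical fibril and the
#: tolerance within which a bed is accepted as geometrically plausible.
SLENDERNESS_TARGET = 5.0
SLENDERNESS_TOL = 2.5

MODE_NONE, MODE_TIP, MODE_SIDE = 0, 1, 2
MODE_NAMES = {MODE_NONE: "none", MODE_TIP: "tip", MODE_SIDE: "side"}

_CONTACT_TIE_TOL = 1.0e-12  # μm; fibrils within this of the boundary contact


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class PadGeometry:
    """Rigid convex envelope of the pad.

    Parameters
    ----------
    dome_radius:
        Radius of curvature of the pad envelope, μm.  ``np.inf`` gives a
        flat pad.
    footprint_area:
        Surface-area ceiling of the pad (projected contact can never exceed
        it), μm².  Defaults to the 0.1 mm² of a euplantula pair.
    apex:
        (x, y) position of the dome apex, μm.
    """

    dome_radius: float = 4000.0
    footprint_area: float = DEFAULT_FOOTPRINT_AREA
    apex: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.dome_radius > 0:
            raise ValueError("dome_radius must be positive")
        if not 0 < self.footprint_area <= DEFAULT_FOOTPRINT_AREA:
            raise ValueError(
                f"footprint_area must lie in (0, {DEFAULT_FOOTPRINT_AREA:g}] μm²"
            )

    @property
    def footprint_radius(self) -> float:
        """Radius of the circular pad footprint, μm."""
        return float(np.sqrt(self.footprint_area / np.pi))

    def sag(self, positions: np.ndarray) -> np.ndarray:
        """Height of the envelope above its apex plane at ``positions``.

        Parabolic approximation of the spherical cap, ρ²/(2R), exact to
        O((ρ/R)⁴) for the shallow domes considered here.
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        rho2 = np.sum((pos - np.asarray(self.apex)) ** 2, axis=1)
        if np.isinf(self.dome_radius):
            return np.zeros_like(rho2)
        return rho2 / (2.0 * self.dome_radius)


@dataclass
class FibrilBed:
    """Geometry and compliance of the fibril (acantha) array.

    ``tip_offsets`` are per-fibril heights *below* the local pad envelope
    (non-coplanarity of the tips); the envelope sag of :class:`PadGeometry`
    is added on top when solving contact.
    """

    positions: np.ndarray  # (n, 2), μm
    tip_offsets: np.ndarray  # (n,), μm, >= 0
    fibril_length: float = 12.0  # μm
    base_radius: float = 1.2  # μm
    tip_radius: float = 0.27  # μm
    axial_stiffness: float = 500.0  # nN/μm
    bending_stiffness: float = 2.5e3  # nN·μm², informational
    critical_side_overlap: float = 1.2  # μm, tip→side transition
    side_stiffness_ratio: float = 0.3  # tangent stiffness ratio past critical
    side_saturation_overlap: float = 10.0  # μm past critical to full side
    tip_area_min: float = TIP_AREA_MIN  # μm²
    side_area_max: float = SIDE_AREA_MAX  # μm²
    aspect_max: float = ASPECT_MAX
    footprint_area: float | None = None  # μm², for density validation

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.tip_offsets = np.asarray(self.tip_offsets, dtype=float).ravel()
        if self.positions.shape[0] != self.tip_offsets.shape[0]:
            raise ValueError("positions and tip_offsets length mismatch")
        if not np.all(np.isfinite(self.tip_offsets)):
            raise ValueError("tip_offsets must be finite")
        if np.any(self.tip_offsets < 0):
            raise ValueError("tip_offsets must be >= 0")
        slenderness = self.fibril_length / (2.0 * self.base_radius)
        if abs(slenderness - SLENDERNESS_TARGET) > SLENDERNESS_TOL:
            raise ValueError(
                f"fibril slenderness {slenderness:.2f} outside the conical "
                f"low-aspect range {SLENDERNESS_TARGET}±{SLENDERNESS_TOL}"
            )
        if self.critical_side_overlap <= 0:
            raise ValueError("critical_side_overlap must be positive")
        if self.footprint_area is not None:
            density = self.n_fibrils / self.footprint_area
            if density > MAX_DENSITY * 1.02:
                raise ValueError(
                    f"areal density {density:.3f} μm⁻² exceeds the "
                    f"{MAX_DENSITY} μm⁻² ceiling"
                )

    @property
    def n_fibrils(self) -> int:
        return int(self.positions.shape[0])

    @property
    def tip_cap_area(self) -> float:
        """Full spherical-cap tip contact area π r_t², μm²."""
        return float(np.pi * self.tip_radius**2)


def tip_area_coverage(density: float, tip_radius: float = 0.27) -> float:
    """Fraction of the pad surface covered by fibril tip caps.

    ``density × π r_t²`` — dimensionless.  With the SEM density ceiling and
    the default tip radius this is below 5%, one of the features keeping
    zero-load contact (and hence adhesion) negligible.
    """
    if density < 0 or tip_radius <= 0:
        raise ValueError("density must be >= 0 and tip_radius > 0")
    return float(density * np.pi * tip_radius**2)


@dataclass
class LoadStep:
    """One loading condition: normal force, optional in-plane shear."""

    F_N: float  # mN
    F_S: float = 0.0  # mN
    shear_direction: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.F_N < 0:
            raise ValueError("F_N must be >= 0")


@dataclass
class ContactState:
    """Solved contact of a bed under one load step.

    Per-fibril arrays are aligned with ``bed.positions``; aggregates follow
    the hierarchical decomposition A_R = A_A · N_A · A_Ac.
    """

    bed: FibrilBed
    pad: PadGeometry
    mode: np.ndarray  # int codes, see MODE_NAMES
    contact_area: np.ndarray  # μm²
    aspect_ratio: np.ndarray  # >= 1
    orientation: np.ndarray  # radians
    normal_force: np.ndarray  # nN
    delta: float  # dome descent, μm
    F_N: float  # mN
    F_S: float = 0.0  # mN
    saturated: bool = False
    A_A: float = 0.0  # projected (hull) area, μm²
    N_A: float = 0.0  # contacting density, μm⁻²
    A_Ac: float = 0.0  # mean per-fibril contact area, μm²
    A_R: float = 0.0  # real contact area, μm²

    @property
    def n_contacts(self) -> int:
        return int(np.count_nonzero(self.mode != MODE_NONE))

    @property
    def contacting(self) -> np.ndarray:
        return self.mode != MODE_NONE


# ---------------------------------------------------------------------------
# per-fibril constitutive law
# ---------------------------------------------------------------------------
def _side_growth_rates(bed: FibrilBed) -> tuple[float, float]:
    """Linear growth rates (μm per μm of post-critical overlap) of the side
    patch length and width, chosen so that patch area reaches
    ``side_area_max`` exactly when the aspect ratio reaches ``aspect_max``,
    at ``side_saturation_overlap`` past the critical point."""
    w0 = 2.0 * bed.tip_radius
    w_star = np.sqrt(4.0 * bed.side_area_max / (np.pi * bed.aspect_max))
    l_star = bed.aspect_max * w_star
    ds = bed.side_saturation_overlap
    c_len = (l_star - w0) / ds
    c_wid = (w_star - w0) / ds
    return c_len, c_wid


def fibril_response(
    overlap: np.ndarray | float,
    bed: FibrilBed,
    shear_bias: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise contact law of a single fibril (vectorised over overlap).

    Parameters
    ----------
    overlap:
        Vertical interference between the fibril tip and the substrate, μm.
    bed:
        Supplies stiffness and patch-geometry parameters.
    shear_bias:
        Dimensionless in [0, 1); lowers the effective critical overlap,
        modelling the increased tendency of sheared fibrils to fall over
        into side contact.

    Returns
    -------
    force, area, aspect, mode:
        nN, μm², dimensionless (≥1) and integer mode codes, each shaped
        like ``overlap``.
    """
    ov = np.asarray(overlap, dtype=float)
    if np.any(ov < 0):
        raise ValueError("overlap must be >= 0")
    if not 0.0 <= shear_bias < 1.0:
        raise ValueError("shear_bias must lie in [0, 1)")
    scalar = ov.ndim == 0
    ov = np.atleast_1d(ov)

    crit = bed.critical_side_overlap * (1.0 - shear_bias)
    k = bed.axial_stiffness
    k_side = bed.side_stiffness_ratio * k
    cap = bed.tip_cap_area
    c_len, c_wid = _side_growth_rates(bed)
    w0 = 2.0 * bed.tip_radius

    mode = np.where(ov > 0, np.where(ov <= crit, MODE_TIP, MODE_SIDE), MODE_NONE)
    force = np.zeros_like(ov)
    area = np.zeros_like(ov)
    aspect = np.ones_like(ov)

    tip = mode == MODE_TIP
    force[tip] = k * ov[tip]
    area[tip] = bed.tip_area_min + (cap - bed.tip_area_min) * ov[tip] / crit

    side = mode == MODE_SIDE
    if np.any(side):
        extra = ov[side] - crit
        force[side] = k * crit + k_side * extra
        extra_eff = np.minimum(extra, bed.side_saturation_overlap)
        length = w0 + c_len * extra_eff
        width = w0 + c_wid * extra_eff
        area[side] = np.minimum(np.pi / 4.0 * length * width, bed.side_area_max)
        aspect[side] = np.minimum(length / width, bed.aspect_max)

    if scalar:
        return force[0], area[0], aspect[0], mode[0]
    return force, area, aspect, mode


# ---------------------------------------------------------------------------
# indentation solver
# ---------------------------------------------------------------------------
def _total_force(delta: float, gaps: np.ndarray, bed: FibrilBed, shear_bias: float) -> float:
    overlap = np.maximum(delta - gaps, 0.0)
    force, _, _, _ = fibril_response(overlap, bed, shear_bias)
    return float(force.sum())


def _patch_hull_area(state_positions: np.ndarray, lengths: np.ndarray,
                     widths: np.ndarray, orient: np.ndarray) -> float:
    """Convex-hull area (μm²) of the contacting patch footprints.

    Each elliptical patch contributes its four axis endpoints so the hull
    encloses patch extents, not just centres."""
    n = state_positions.shape[0]
    if n == 0:
        return 0.0
    cos, sin = np.cos(orient), np.sin(orient)
    u = np.stack([cos, sin], axis=1) * (lengths / 2.0)[:, None]
    v = np.stack([-sin, cos], axis=1) * (widths / 2.0)[:, None]
    pts = np.concatenate([
        state_positions + u, state_positions - u,
        state_positions + v, state_positions - v,
    ])
    try:
        return float(ConvexHull(pts).volume)  # 2-D: volume == area
    except QhullError:
        # degenerate (collinear / single patch): fall back to summed areas
        return float(np.sum(np.pi / 4.0 * lengths * widths))


def _assemble_state(
    bed: FibrilBed, pad: PadGeometry, delta: float, F_N: float,
    shear_bias: float, F_S: float = 0.0, shear_direction: float | None = None,
    saturated: bool = False,
) -> ContactState:
    gaps = pad.sag(bed.positions) + bed.tip_offsets
    # fibrils within the tie tolerance of the boundary count as contacting
    # (assigned an infinitesimal positive overlap)
    raw = delta - gaps
    raw[(raw > -_CONTACT_TIE_TOL) & (raw <= 0.0) & (delta > 0.0)] = _CONTACT_TIE_TOL
    overlap = np.maximum(raw, 0.0)
    force, area, aspect, mode = fibril_response(overlap, bed, shear_bias)

    # patch orientation: radial from the apex by default (peripheral fibrils
    # bend outward following the pad curvature); along the shear direction
    # once an external shear is applied.
    rel = bed.positions - np.asarray(pad.apex)
    orient = np.arctan2(rel[:, 1], rel[:, 0])
    if shear_direction is not None:
        orient = np.full(bed.n_fibrils, float(shear_direction))
    orient = np.where(mode == MODE_SIDE, orient, 0.0)

    contacting = mode != MODE_NONE
    n = int(np.count_nonzero(contacting))
    if n:
        widths = np.sqrt(4.0 * area[contacting] / (np.pi * aspect[contacting]))
        lengths = aspect[contacting] * widths
        A_A = _patch_hull_area(bed.positions[contacting], lengths, widths,
                               orient[contacting])
        A_A = min(A_A, pad.footprint_area)
        N_A = n / A_A
        A_Ac = float(area[contacting].mean())
    else:
        A_A = N_A = A_Ac = 0.0

    return ContactState(
        bed=bed, pad=pad, mode=mode, contact_area=area, aspect_ratio=aspect,
        orientation=orient, normal_force=force, delta=delta, F_N=F_N, F_S=F_S,
        saturated=saturated, A_A=A_A, N_A=N_A, A_Ac=A_Ac,
        A_R=A_A * N_A * A_Ac,
    )


def solve_indentation(
    bed: FibrilBed,
    pad: PadGeometry,
    step: LoadStep | float,
    shear_bias: float = 0.0,
    rel_tol: float = 1.0e-6,
    abs_tol_nN: float = 1.0e-3,
    max_descent: float = 1.0e4,
) -> ContactState:
    """Solve the dome descent δ at which fibril forces balance the load.

    The total force is continuous and non-decreasing in δ, so a bracketing
    bisection converges unconditionally; iteration stops once the force
    residual is below ``max(rel_tol·F_N, abs_tol_nN)``.  A fibril contacts
    when the descent exceeds its envelope gap (dome sag at its position plus
    its tip offset); boundary ties within 1e-12 μm count as contacting.
    """
    if not isinstance(step, LoadStep):
        step = LoadStep(F_N=float(step))
    if step.F_N == 0.0:
        return _assemble_state(bed, pad, 0.0, 0.0, shear_bias)

    target = step.F_N * NN_PER_MN
    tol = max(rel_tol * target, abs_tol_nN)
    gaps = pad.sag(bed.positions) + bed.tip_offsets

    lo, hi = 0.0, float(gaps.min()) + 1.0
    while _total_force(hi, gaps, bed, shear_bias) < target:
        hi *= 2.0
        if hi > max_descent:
            warnings.warn(
                "load exceeds the bed's capacity within the allowed descent; "
                "returning the saturated state", RuntimeWarning, stacklevel=2)
            return _assemble_state(bed, pad, max_descent, step.F_N,
                                   shear_bias, saturated=True)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = _total_force(mid, gaps, bed, shear_bias)
        if abs(f - target) <= tol:
            break
        if f < target:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
    return _assemble_state(bed, pad, mid, step.F_N, shear_bias)


def apply_shear(
    state: ContactState,
    F_S: float,
    direction: float = 0.0,
    shear_sensitivity: float = 0.2,
) -> ContactState:
    """Re-solve a contact state under an added in-plane shear force.

    Shear biases fibrils toward side contact (lower effective critical
    overlap) and aligns side-contact patch orientations with ``direction``.
    ``F_S = 0`` returns the state unchanged; reversing ``direction`` flips
    orientations by π without changing any contact area.
    """
    if F_S < 0:
        raise ValueError("F_S must be >= 0")
    if F_S == 0.0:
        return state
    bias = min(0.9, shear_sensitivity * F_S)
    new = solve_indentation(state.bed, state.pad, LoadStep(state.F_N),
                            shear_bias=bias)
    return replace(
        new,
        F_S=F_S,
        orientation=np.where(new.mode == MODE_SIDE,
                             float(direction) % (2 * np.pi), 0.0),
    )


def state_to_frame(state: ContactState) -> pd.DataFrame:
    """Per-fibril dump of a contact state (debugging / CSV export)."""
    return pd.DataFrame({
        "x_um": state.bed.positions[:, 0],
        "y_um": state.bed.positions[:, 1],
        "mode": [MODE_NAMES[int(m)] for m in state.mode],
        "contact_area_um2": state.contact_area,
        "aspect_ratio": state.aspect_ratio,
        "orientation_rad": state.orientation,
        "normal_force_nN": state.normal_force,
    })


def sweep_loads(
    bed: FibrilBed,
    pad: PadGeometry,
    loads: Sequence[float],
    individual_id: str | int | None = None,
) -> pd.DataFrame:
    """Solve a load sweep and tabulate the three-level contact observables.

    Returns one row per load with columns ``load_mN``, ``A_A_mm2``,
    ``N_A_per_um2``, ``A_Ac_um2``, ``A_R_um2``, ``delta_um``, ``n_contacts``
    and ``saturated``.  Loads must be sorted ascending.  The solver is
    stateless (purely elastic, no plasticity), so unloading retraces the
    same states.
    """
    loads = list(loads)
    if any(l <= 0 for l in loads):
        raise ValueError("loads must be strictly positive")
    if sorted(loads) != loads:
        raise ValueError("loads must be sorted ascending")
    rows = []
    for load in loads:
        st = solve_indentation(bed, pad, load)
        row = {
            "load_mN": load,
            "A_A_mm2": st.A_A / UM2_PER_MM2,
            "N_A_per_um2": st.N_A,
            "A_Ac_um2": st.A_Ac,
            "A_R_um2": st.A_R,
            "delta_um": st.delta,
            "n_contacts": st.n_contacts,
            "saturated": st.saturated,
        }
        if individual_id is not None:
            row = {"individual_id": individual_id, **row}
        rows.append(row)
    return pd.DataFrame(rows)
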