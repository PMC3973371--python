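"""Friction laws for fibrillar pads, rigid solids and adhesive spheres.

Friction is taken as proportional to real contact area through a constant
interfacial shear stress τ: F_F = τ·A_R.  How A_R grows with normal load
then fully determines the friction law:

* **Amonton / adhesion-extended** — F_F = μ(F_N + F_A); the intercept of a
  friction–load regression is F_0 = μ·F_A, an adhesion-equivalent load.
* **Power-law pad** — A_R = a·F_N^k with 0 < k < 1 composed from the three
  hierarchical contact levels; the apparent friction coefficient
  μ_app = τ·a·F_N^(k−1) then *decreases* with load.
* **Rigid solid** — A_R = C·F_N with a minute growth rate C, giving the
  classic load-independent μ = τ·C.
* **JKR sphere** — adhesive elastic sphere with finite contact (and hence
  friction) at zero load and pull-off force (3/2)πWR.

Unit conventions live in one place: stresses in MPa (1 MPa = 10³ nN/μm²),
forces in mN, areas in mm² or μm² as stated per function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .padmech import KPA_PER_MPA, NN_PER_MN, UM2_PER_MM2
from .scalestats import FriedmanResult, friedman_test, median_mad

#: mN per mm² in one MPa (τ[MPa]·A[mm²] → force in mN needs this factor).
MN_PER_MM2_PER_MPA = 1.0e3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class FrictionFit:
    """Extended-Amonton fit F_F = μ·F_N + F_0 with F_0 = μ·F_A."""

    mu: float
    F0: float  # mN, friction at zero normal load
    F_adh: float | None  # mN; None when μ <= 0 makes it undefined
    residuals: np.ndarray

    @property
    def adhesion_defined(self) -> bool:
        return self.F_adh is not None


@dataclass
class JKRParams:
    """Adhesive elastic sphere: radius R (μm), work of adhesion W (mN/m),
    reduced contact modulus K = 4E*/3 (MPa)."""

    R: float = 180.0
    W: float = 60.0
    K: float = 4.0 / 3.0  # from the 1 MPa effective stiffness E*

    def __post_init__(self) -> None:
        if self.R <= 0 or self.K <= 0:
            raise ValueError("R and K must be positive")
        if self.W < 0:
            raise ValueError("W must be >= 0")

    @property
    def pull_off_nN(self) -> float:
        """Magnitude of the pull-off force (3/2)πWR, nN.

        1 mN/m ≡ 1 nN/μm, so W·R is already in nN.
        """
        return 1.5 * np.pi * self.W * self.R

    @property
    def zero_load_radius_um(self) -> float:
        """Contact radius at F = 0: a³ = 6πWR²/K."""
        K_int = self.K * KPA_PER_MPA  # nN/μm²
        return float((6.0 * np.pi * self.W * self.R**2 / K_int) ** (1.0 / 3.0))


@dataclass
class MaterialSpec:
    """One material line of a contact-area-versus-load comparison."""

    name: str
    law: str  # 'power_law', 'linear_C' or 'jkr'
    tau_MPa: float = 1.0
    C_mm2_per_mN: float | None = None  # linear_C
    prefactor_mm2: float | None = None  # power_law: A_R(1 mN), mm²
    exponent: float | None = None  # power_law
    jkr: JKRParams | None = None

    def __post_init__(self) -> None:
        if self.law == "linear_C" and self.C_mm2_per_mN is None:
            raise ValueError("linear_C law needs C_mm2_per_mN")
        if self.law == "power_law" and (self.prefactor_mm2 is None
                                        or self.exponent is None):
            raise ValueError("power_law needs prefactor_mm2 and exponent")
        if self.law == "jkr" and self.jkr is None:
            raise ValueError("jkr law needs JKRParams")
        if self.law not in ("power_law", "linear_C", "jkr"):
            raise ValueError(f"unknown law {self.law!r}")


# ---------------------------------------------------------------------------
# Amonton fits
# ---------------------------------------------------------------------------
def fit_amonton_extended(
    loads_mN: Sequence[float], friction_mN: Sequence[float],
) -> FrictionFit:
    """OLS of friction medians over load: slope μ, intercept F_0, and the
    implied adhesion-equivalent load F_A = F_0/μ.

    Intended for per-load median friction values (robust against the skewed
    friction distributions), but accepts any paired series of ≥2 points.
    μ ≤ 0 leaves F_A undefined (None).
    """
    x = np.asarray(loads_mN, dtype=float)
    y = np.asarray(friction_mN, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need >= 2 paired (load, friction) points")
    X = np.column_stack([x, np.ones_like(x)])
    (mu, F0), *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - (mu * x + F0)
    F_adh = float(F0 / mu) if mu > 0 else None
    return FrictionFit(mu=float(mu), F0=float(F0), F_adh=F_adh,
                       residuals=resid)


# ---------------------------------------------------------------------------
# shear stress
# ---------------------------------------------------------------------------
@dataclass
class ShearStressReport:
    """Per-observation shear stresses with a constancy assessment."""

    tau_MPa: np.ndarray
    median: float
    mad: float
    friedman: FriedmanResult | None  # None when no repeated-measures layout


def shear_stress_series(
    friction_mN: Sequence[float],
    A_R_um2: Sequence[float],
    obs: pd.DataFrame | None = None,
    group: str = "individual_id",
    load_col: str = "load_mN",
) -> ShearStressReport:
    """Friction corrected for real contact area: τ = F_F/A_R per
    observation, in MPa.

    If ``obs`` provides the individual × load layout, constancy of τ across
    loads is assessed with Friedman's test (the friction-corrected analogue
    of the raw friction–load test); the summary is median ± MAD.  Zero A_R
    with non-zero friction is an error.
    """
    F = np.asarray(friction_mN, dtype=float)
    A = np.asarray(A_R_um2, dtype=float)
    if F.shape != A.shape:
        raise ValueError("friction and A_R must be the same length")
    if np.any((A <= 0) & (F != 0)):
        raise ValueError("zero real contact area with non-zero friction")
    tau = np.zeros_like(F)
    nz = A > 0
    # mN/μm² → MPa: ×1e6 (nN/mN) / 1e3 (nN/μm² per MPa)
    tau[nz] = F[nz] / A[nz] * NN_PER_MN / KPA_PER_MPA
    med, mad = median_mad(tau)

    fr = None
    if obs is not None:
        wide = (obs.assign(tau=tau)
                .pivot(index=group, columns=load_col, values="tau"))
        if wide.shape[0] >= 2 and wide.shape[1] >= 2 and not wide.isna().any().any():
            fr = friedman_test(wide.to_numpy())
    return ShearStressReport(tau_MPa=tau, median=med, mad=mad, friedman=fr)


# ---------------------------------------------------------------------------
# apparent and rigid friction coefficients
# ---------------------------------------------------------------------------
def apparent_mu(
    tau_MPa: float, prefactor_mm2: float, k: float,
    F_N_mN: np.ndarray | float,
) -> np.ndarray | float:
    """Load-dependent friction coefficient of a power-law pad.

    With A_R = a·F^k (mm², mN) and constant τ, friction is
    F_F = τ·a·F^k, so μ_app = F_F/F_N = τ·a·F^(k−1): the log–log slope of
    μ_app over load is k−1 (negative for the sublinear pad hierarchy).
    """
    F = np.asarray(F_N_mN, dtype=float)
    if np.any(F <= 0):
        raise ValueError("F_N must be > 0")
    out = tau_MPa * MN_PER_MM2_PER_MPA * prefactor_mm2 * F ** (k - 1.0)
    return float(out) if out.ndim == 0 else out


def rigid_mu(tau_MPa: float, C_mm2_per_mN: float) -> float:
    """Friction coefficient of a rigid solid: μ = τ·C.

    τ in MPa = 10³ mN/mm², C in mm²/mN, so μ = τ·10³·C (dimensionless).
    Steel on steel (τ ≈ 800 MPa, C ≈ 10⁻⁶ mm²/mN) gives μ ≈ 0.8.
    """
    if tau_MPa < 0 or C_mm2_per_mN < 0:
        raise ValueError("tau and C must be >= 0")
    return float(tau_MPa * MN_PER_MM2_PER_MPA * C_mm2_per_mN)


def growth_rate_C(
    loads_mN: Sequence[float], A_R_mm2: Sequence[float],
) -> float:
    """Growth rate C of real contact area with load: OLS slope of
    A_R (mm²) on F_N (mN)."""
    x = np.asarray(loads_mN, dtype=float)
    y = np.asarray(A_R_mm2, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need >= 2 paired points")
    X = np.column_stack([x, np.ones_like(x)])
    (slope, _), *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(slope)


# ---------------------------------------------------------------------------
# JKR sphere
# ---------------------------------------------------------------------------
def jkr_contact(
    F_mN: np.ndarray | float, params: JKRParams,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """JKR contact radius (μm) and area (μm²) of an adhesive sphere.

    a³ = (R/K)·(F + 3πWR + √(6πWRF + (3πWR)²)), with W → 0 recovering the
    Hertz limit a³ = RF/K.  Loads below the pull-off force −(3/2)πWR
    raise (contact lost).
    """
    F = np.asarray(F_mN, dtype=float) * NN_PER_MN  # nN
    K = params.K * KPA_PER_MPA  # nN/μm²
    wr3pi = 3.0 * np.pi * params.W * params.R  # nN (mN/m ≡ nN/μm)
    disc = 6.0 * np.pi * params.W * params.R * F + wr3pi**2
    if np.any(disc < -1e-9 * max(wr3pi**2, 1.0)) or np.any(F < -0.5 * wr3pi - 1e-9):
        raise ValueError("load below the JKR pull-off force: contact lost")
    disc = np.maximum(disc, 0.0)
    a3 = params.R / K * (F + wr3pi + np.sqrt(disc))
    a = np.cbrt(a3)
    area = np.pi * a**2
    if a.ndim == 0:
        return float(a), float(area)
    return a, area


# ---------------------------------------------------------------------------
# adhesion per unit area
# ---------------------------------------------------------------------------
def adhesion_per_area(force_nN: float, area_um2: float) -> float:
    """Adhesive stress in MPa from a pull-off force (nN) and contact area
    (μm²): nN/μm² = kPa, so divide by 10³."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return float(force_nN / area_um2 / KPA_PER_MPA)


# ---------------------------------------------------------------------------
# material comparison curves
# ---------------------------------------------------------------------------
def figure_material_curves(
    materials: Sequence[MaterialSpec],
    loads_mN: Sequence[float],
) -> pd.DataFrame:
    """Real contact area over a load grid for a set of materials.

    Long-format table (material, load_mN, A_R_mm2) contrasting the
    power-law pad (negligible area at near-zero load, rapid growth), the
    rigid linear-C solid (straight line through the origin) and the JKR
    sphere (finite area at zero load).
    """
    loads = np.asarray(loads_mN, dtype=float)
    rows = []
    for mat in materials:
        if mat.law == "power_law":
            area = mat.prefactor_mm2 * np.maximum(loads, 0.0) ** mat.exponent
        elif mat.law == "linear_C":
            area = mat.C_mm2_per_mN * loads
        else:  # jkr
            _, area_um2 = jkr_contact(loads, mat.jkr)
            area = np.asarray(area_um2) / UM2_PER_MM2
        for load, a in zip(loads, np.asarray(area, dtype=float)):
            rows.append({"material": mat.name, "load_mN": float(load),
                         "A_R_mm2": float(a)})
    return pd.DataFrame(rows)
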