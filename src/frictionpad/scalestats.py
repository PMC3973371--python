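"""Scaling statistics for repeated-measures contact-area data.

The unit of analysis is one individual × one normal load (a
``PadObservation`` row).  The real contact area decomposes hierarchically as

    A_R = A_A · N_A · A_Ac

(projected contact area × density of contacting fibrils × mean per-fibril
contact area), and each factor follows an empirical power law in normal
load, ``y = a · F_N^k``.  Exponents are estimated on log10–log10 data with a
linear mixed model: fixed slope and intercept, a random intercept per
individual (the repeated-measures structure), fitted by restricted maximum
likelihood profiled over the variance ratio λ = σ²_between/σ²_residual and
optimised by bounded scalar search.  Goodness of fit is reported as
marginal R² (fixed-effect variance share) and conditional R² (fixed plus
random), following Nakagawa & Schielzeth's variance-decomposition method.

Also here: Friedman's repeated-measures rank test (with tie correction),
repeated-measures ANCOVA η² with a bootstrap CI, and the summary
conventions mean ± t-based margin and median ± MAD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .padmech import UM2_PER_MM2

logger = logging.getLogger("frictionpad")

#: Observation-table schema shared across the package.
OBS_COLUMNS = ("individual_id", "load_mN", "A_A_mm2", "N_A_per_um2",
               "A_Ac_um2")
RESPONSE_COLUMNS = ("A_A_mm2", "N_A_per_um2", "A_Ac_um2", "A_R_um2")


# ---------------------------------------------------------------------------
# Eq A_R = A_A · N_A · A_Ac
# ---------------------------------------------------------------------------
def real_contact_area(A_A_mm2, N_A_per_um2, A_Ac_um2):
    """Real contact area in μm² from the three-level decomposition.

    ``A_R = (A_A × 10⁶) × N_A × A_Ac`` — the projected area is converted
    from mm² to μm² so all factors share the μm scale.  Accepts scalars or
    arrays; negative inputs raise.
    """
    A_A = np.asarray(A_A_mm2, dtype=float)
    N_A = np.asarray(N_A_per_um2, dtype=float)
    A_Ac = np.asarray(A_Ac_um2, dtype=float)
    if np.any(A_A < 0) or np.any(N_A < 0) or np.any(A_Ac < 0):
        raise ValueError("areas and densities must be >= 0")
    out = A_A * UM2_PER_MM2 * N_A * A_Ac
    return float(out) if out.ndim == 0 else out


def add_real_contact_area(obs: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of an observation table with the A_R_um2 column
    (re)computed from the decomposition."""
    out = obs.copy()
    out["A_R_um2"] = real_contact_area(
        obs["A_A_mm2"], obs["N_A_per_um2"], obs["A_Ac_um2"])
    return out


# ---------------------------------------------------------------------------
# random-intercept power-law fit
# ---------------------------------------------------------------------------
@dataclass
class PowerLawFit:
    """One log10–log10 scaling fit (a scaling-table row).

    ``slope`` is the scaling coefficient k in y = a·F^k; ``intercept`` is
    log10(a).  Variance components are on the log10 response scale.
    """

    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    r2_conditional: float
    r2_marginal: float
    sigma2_between: float
    sigma2_residual: float
    n_individuals: int
    n_obs: int
    method: str  # 'reml', 'exact' (zero residual) or 'ols' (singular fit)

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2_marginal <= self.r2_conditional <= 1 + 1e-9):
            raise ValueError("R² ordering violated: need "
                             "0 <= marginal <= conditional <= 1")

    @property
    def prefactor(self) -> float:
        """a = 10^intercept, in the response's own units."""
        return 10.0**self.intercept


def _reml_profile(lam: float, y: np.ndarray, X: np.ndarray,
                  groups: np.ndarray):
    """GLS estimates and REML deviance at variance ratio λ (block-diagonal
    V = I + λ·J per group, solved group-wise by Woodbury)."""
    n, p = X.shape
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    logdetV = 0.0
    for g in np.unique(groups):
        m = groups == g
        ni = int(m.sum())
        c = lam / (1.0 + lam * ni)
        Xg, yg = X[m], y[m]
        XtViX += Xg.T @ Xg - c * np.outer(Xg.sum(0), Xg.sum(0))
        XtViy += Xg.T @ yg - c * Xg.sum(0) * yg.sum()
        logdetV += np.log1p(lam * ni)
    beta = np.linalg.solve(XtViX, XtViy)
    # r' V^-1 r, group-wise
    quad = 0.0
    for g in np.unique(groups):
        m = groups == g
        ni = int(m.sum())
        c = lam / (1.0 + lam * ni)
        rg = y[m] - X[m] @ beta
        quad += rg @ rg - c * rg.sum() ** 2
    sigma2 = quad / (n - p)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    dev = (n - p) * np.log(max(sigma2, 1e-300)) + logdetV + logdetXtViX
    return beta, sigma2, XtViX, dev


def fit_powerlaw_mixed(
    obs: pd.DataFrame,
    response: str,
    group: str = "individual_id",
    load_col: str = "load_mN",
) -> PowerLawFit:
    """Fit log10(response) ~ log10(load) with a random intercept per group.

    Restricted maximum likelihood, profiled over the between/within variance
    ratio and optimised by bounded scalar search on its logarithm.  Marginal
    and conditional R² follow the Nakagawa–Schielzeth decomposition.  A
    singular fit (between-individual variance indistinguishable from zero)
    falls back to pooled OLS with a logged note; an exactly line-on-line
    dataset (zero residual variance) is returned via a closed-form path
    with conditional R² = 1.
    """
    for col in (response, group, load_col):
        if col not in obs.columns:
            raise ValueError(f"column {col!r} missing from observations")
    bad = obs.index[~(obs[response] > 0)].tolist()
    if bad:
        raise ValueError(
            f"non-positive {response} values in rows {bad}: power-law fits "
            "need strictly positive responses")
    groups = obs[group].to_numpy()
    ug = np.unique(groups)
    if len(ug) < 2:
        raise ValueError("need at least 2 individuals")
    if obs.groupby(group)[load_col].count().min() < 2:
        raise ValueError("need at least 2 loads per individual")

    x = np.log10(obs[load_col].to_numpy(dtype=float))
    y = np.log10(obs[response].to_numpy(dtype=float))
    n = len(y)
    X = np.column_stack([np.ones(n), x])

    # exact-fit detection: least squares with group dummies
    D = (groups[:, None] == ug[None, :]).astype(float)
    Xf = np.column_stack([x, D])
    coef, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    resid = y - Xf @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    if float(resid @ resid) <= max(1e-18, 1e-12 * sst):
        slope = float(coef[0])
        intercepts = coef[1:]
        s2_b = float(np.var(intercepts))
        s2_f = float(np.var(slope * x))
        tot = s2_f + s2_b
        return PowerLawFit(
            intercept=float(np.mean(intercepts)), intercept_se=0.0,
            slope=slope, slope_se=0.0,
            r2_conditional=1.0,
            r2_marginal=s2_f / tot if tot > 0 else 1.0,
            sigma2_between=s2_b, sigma2_residual=0.0,
            n_individuals=len(ug), n_obs=n, method="exact")

    res = minimize_scalar(
        lambda loglam: _reml_profile(np.exp(loglam), y, X, groups)[3],
        bounds=(-30.0, 30.0), method="bounded",
        options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    method = "reml"
    if lam < 1e-7:  # singular: no detectable between-individual variance
        logger.info("fit_powerlaw_mixed(%s): between-individual variance "
                    "indistinguishable from zero; falling back to pooled OLS",
                    response)
        lam = 0.0
        method = "ols"
    beta, sigma2, XtViX, _ = _reml_profile(lam, y, X, groups)
    cov = np.linalg.inv(XtViX) * sigma2
    se = np.sqrt(np.diag(cov))
    s2_e = float(sigma2)
    s2_b = float(lam * sigma2)
    s2_f = float(np.var(beta[1] * x))
    tot = s2_f + s2_b + s2_e
    return PowerLawFit(
        intercept=float(beta[0]), intercept_se=float(se[0]),
        slope=float(beta[1]), slope_se=float(se[1]),
        r2_conditional=(s2_f + s2_b) / tot,
        r2_marginal=s2_f / tot,
        sigma2_between=s2_b, sigma2_residual=s2_e,
        n_individuals=len(ug), n_obs=n, method=method)


@dataclass
class ComposedExponent:
    """Power-law composition of the three contact-area levels."""

    k_sum: float
    k_sum_se: float
    prefactor_um2: float  # composed A_R prefactor at 1 mN, μm²
    near_linear: bool


def exponent_composition(
    fit_AA: PowerLawFit, fit_NA: PowerLawFit, fit_AAc: PowerLawFit,
) -> ComposedExponent:
    """Compose the A_R scaling from the three component fits.

    Multiplying the three power laws gives A_R ∝ F^(k_AA + k_NA + k_AAc);
    the composed prefactor folds in the mm²→μm² conversion of the projected
    area.  ``near_linear`` flags |Σk − 1| ≤ 0.2 — the regime where the
    hierarchy's sublinear levels combine to an almost proportional growth
    of real contact area with load.
    """
    k_sum = fit_AA.slope + fit_NA.slope + fit_AAc.slope
    se = float(np.sqrt(fit_AA.slope_se**2 + fit_NA.slope_se**2
                       + fit_AAc.slope_se**2))
    prefactor = (fit_AA.prefactor * UM2_PER_MM2
                 * fit_NA.prefactor * fit_AAc.prefactor)
    return ComposedExponent(
        k_sum=float(k_sum), k_sum_se=se, prefactor_um2=float(prefactor),
        near_linear=bool(abs(k_sum - 1.0) <= 0.2))


# ---------------------------------------------------------------------------
# Friedman's repeated-measures rank test
# ---------------------------------------------------------------------------
class FriedmanResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def friedman_test(matrix: np.ndarray | pd.DataFrame) -> FriedmanResult:
    """Friedman's test (repeated-measures ANOVA on ranks) on an
    individuals × conditions matrix.

    Within-row mid-ranks with the standard tie correction; the χ² statistic
    has k−1 degrees of freedom and the p-value comes from the asymptotic χ²
    distribution.  A matrix whose rows are entirely tied (e.g. identical
    columns) returns χ²=0, p=1.  Missing cells raise (no imputation).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (individuals × conditions)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 individuals and 2 conditions")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not allowed (no imputation)")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    Rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3.0 * n * (k + 1)
    tie = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie += float(np.sum(counts**3 - counts))
    corr = 1.0 - tie / (n * k * (k**2 - 1))
    if corr <= 0:  # every row fully tied
        return FriedmanResult(0.0, k - 1, 1.0)
    chi2 /= corr
    chi2 = max(chi2, 0.0)
    return FriedmanResult(float(chi2), k - 1,
                          float(stats.chi2.sf(chi2, k - 1)))


# ---------------------------------------------------------------------------
# repeated-measures ANCOVA effect size
# ---------------------------------------------------------------------------
@dataclass
class EffectSize:
    F: float
    df1: int
    df2: int
    pvalue: float
    eta_squared: float
    ci_low: float
    ci_high: float


def _eta2_decomposition(y, x, groups):
    ug = np.unique(groups)
    D = (groups[:, None] == ug[None, :]).astype(float)
    sst = float(np.sum((y - y.mean()) ** 2))

    def ssr(Xd):
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        r = y - Xd @ coef
        return float(r @ r)

    ssr_block = ssr(D)
    ssr_full = ssr(np.column_stack([D, x]))
    ss_load = ssr_block - ssr_full
    df2 = len(y) - len(ug) - 1
    return ss_load, ssr_full, sst, df2


def rm_effect_size(
    obs: pd.DataFrame,
    response: str,
    covariate: str = "load_mN",
    group: str = "individual_id",
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> EffectSize:
    """Repeated-measures ANCOVA effect of the covariate on a response.

    Individuals enter as the blocking factor; η² = SS_covariate/SS_total is
    the fraction of total variance accounted for by the load.  The
    confidence interval is a seeded percentile bootstrap over individuals
    (resampling whole individuals preserves the repeated-measures
    structure).  Requires a balanced layout (same loads for every
    individual).
    """
    layout = obs.groupby(group)[covariate].apply(
        lambda s: tuple(sorted(s)))
    if layout.nunique() != 1:
        raise ValueError("unbalanced design: every individual must be "
                         "observed at the same covariate values")
    y = obs[response].to_numpy(dtype=float)
    x = obs[covariate].to_numpy(dtype=float)
    groups = obs[group].to_numpy()

    ss_load, ssr_full, sst, df2 = _eta2_decomposition(y, x, groups)
    F = (ss_load / 1.0) / (ssr_full / df2) if ssr_full > 0 else np.inf
    eta2 = ss_load / sst if sst > 0 else 0.0
    pval = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0

    rng = np.random.default_rng(seed)
    ug = np.unique(groups)
    boots = np.empty(n_boot)
    by_group = {g: (y[groups == g], x[groups == g]) for g in ug}
    for b in range(n_boot):
        pick = rng.choice(ug, size=len(ug), replace=True)
        yb = np.concatenate([by_group[g][0] for g in pick])
        xb = np.concatenate([by_group[g][1] for g in pick])
        gb = np.repeat(np.arange(len(pick)), [len(by_group[g][0]) for g in pick])
        ss_l, _, sst_b, _ = _eta2_decomposition(yb, xb, gb)
        boots[b] = ss_l / sst_b if sst_b > 0 else 0.0
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return EffectSize(F=float(F), df1=1, df2=int(df2), pvalue=pval,
                      eta_squared=float(eta2), ci_low=float(lo),
                      ci_high=float(hi))


# ---------------------------------------------------------------------------
# summary conventions
# ---------------------------------------------------------------------------
def mean_t_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Mean and margin of error (half the CI width) from a t-distribution.

    ``margin = t_{(1+level)/2, n−1} · s/√n`` — the per-load summary-table
    reporting convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a t-based CI")
    tcrit = stats.t.ppf((1 + level) / 2.0, v.size - 1)
    margin = tcrit * v.std(ddof=1) / np.sqrt(v.size)
    return float(v.mean()), float(margin)


def median_mad(values: Sequence[float]) -> tuple[float, float]:
    """Median and raw (unscaled) median absolute deviation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))


# ---------------------------------------------------------------------------
# tabular reports
# ---------------------------------------------------------------------------
def summarize_by_load(
    obs: pd.DataFrame,
    columns: Sequence[str] = ("A_A_mm2", "N_A_per_um2", "A_Ac_um2"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-load summary table: mean ± t-based margin, per column."""
    rows = []
    for load, sub in obs.groupby("load_mN"):
        rec = {"load_mN": load, "n": len(sub)}
        for col in columns:
            mean, margin = mean_t_ci(sub[col].to_numpy(), level)
            rec[f"{col}_mean"] = mean
            rec[f"{col}_margin"] = margin
        rows.append(rec)
    return pd.DataFrame(rows).sort_values("load_mN").reset_index(drop=True)


def fit_all_responses(obs: pd.DataFrame) -> pd.DataFrame:
    """Scaling-fit table: one mixed-model power-law fit per response.

    Fits A_A, N_A, A_Ac and A_R (recomputed from the decomposition if
    absent) and appends the composed exponent row.
    """
    if "A_R_um2" not in obs.columns:
        obs = add_real_contact_area(obs)
    fits = {col: fit_powerlaw_mixed(obs, col) for col in RESPONSE_COLUMNS}
    comp = exponent_composition(fits["A_A_mm2"], fits["N_A_per_um2"],
                                fits["A_Ac_um2"])
    rows = [{
        "parameter": col,
        "intercept": f.intercept, "intercept_se": f.intercept_se,
        "slope": f.slope, "slope_se": f.slope_se,
        "r2_conditional": f.r2_conditional, "r2_marginal": f.r2_marginal,
        "method": f.method,
    } for col, f in fits.items()]
    rows.append({
        "parameter": "composed_A_R", "intercept": np.log10(comp.prefactor_um2),
        "intercept_se": np.nan, "slope": comp.k_sum,
        "slope_se": comp.k_sum_se, "r2_conditional": np.nan,
        "r2_marginal": np.nan, "method": "composition",
    })
    return pd.DataFrame(rows)
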