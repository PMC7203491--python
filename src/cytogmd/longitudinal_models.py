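"""Random-coefficient regression (RCR) of regional GMD and MMSE over time.

The workhorse model is a linear mixed model with per-subject random
intercepts and slopes (unstructured 2x2 covariance, REML): GMD for one
region is modelled as a function of months since the 1st MRI, diagnostic
group (HC reference), age at 1st MRI and gender.  The intercept is then
the age/gender-adjusted HC mean at the 1st MRI, the group coefficient the
AD-HC baseline difference, the time coefficient the HC monthly slope and
the group x time interaction the AD-HC slope difference.  An AD-only
variant (intercept + time) supplies the (beta0, beta1) pair used by the
detection-interval statistic.

Longitudinal fits use only the first scan of each session; duplicate
same-session scans are the province of the reliability analyses and would
otherwise distort the residual variance.

Noise-free inputs (exactly linear trajectories) are detected and solved
deterministically, since the mixed-model likelihood degenerates when the
residual variance is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

__all__ = [
    "RCRFit",
    "fit_rcr_region",
    "group_percent_difference",
    "mmse_trend",
    "change_change_rcr",
    "MMSETrendResult",
    "ChangeChangeResult",
]


@dataclass(frozen=True)
class RCRFit:
    """Fixed-effect estimates and covariance from a random-coefficient fit."""

    params: pd.Series
    cov: pd.DataFrame
    cov_re: np.ndarray | None
    resid_var: float
    converged: bool
    singular_refit: bool
    loglik: float
    n_obs: int
    n_subjects: int
    exact: bool = False
    groups_mode: str = "both"

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def wald(self, name: str, level: float = 0.95):
        """(estimate, (lower, upper), p) for one fixed effect."""
        est = float(self.params[name])
        se = self.se(name)
        return _wald_triplet(est, se, level)

    def contrast(self, weights: dict[str, float], level: float = 0.95):
        """(estimate, (lower, upper), p) for a linear combination."""
        c = np.array([weights.get(n, 0.0) for n in self.params.index])
        est = float(c @ self.params.values)
        se = float(np.sqrt(c @ self.cov.values @ c))
        return _wald_triplet(est, se, level)


def _wald_triplet(est: float, se: float, level: float = 0.95):
    if se == 0.0:
        return est, (est, est), (1.0 if est == 0.0 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(est) / se)
    return est, (est - z * se, est + z * se), p


def _first_scans(table: pd.DataFrame) -> pd.DataFrame:
    """Keep the first scan of each session (replicate index 1)."""
    if "replicate" in table.columns:
        return table[table["replicate"] == 1]
    return table


def _fit_lmm(
    y: np.ndarray,
    design: pd.DataFrame,
    subjects: np.ndarray,
    random_slope_col: str | None,
) -> tuple:
    """Fit a mixed model with random intercept (+ optional random slope).

    Returns (params, cov, cov_re, resid_var, converged, singular_refit,
    loglik, exact).  Exactly linear data (zero residuals under OLS) take a
    deterministic least-squares path with zero covariance.
    """
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    scale = max(1.0, float(np.abs(y).max()))
    if float(resid @ resid) < 1e-18 * scale**2 and rank == x.shape[1]:
        params = pd.Series(beta, index=names)
        cov = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
        return params, cov, None, 0.0, True, False, float("nan"), True

    # Column rescaling for optimizer conditioning: regressors such as
    # months (0-24) against densities of order 0.5 put the variance
    # components on wildly different scales; fit on unit-max-abs columns
    # and transform estimates back exactly afterwards.
    col_scale = np.array(
        [max(float(np.abs(x[:, j]).max()), 1e-12) for j in range(x.shape[1])]
    )
    x = x / col_scale
    if random_slope_col is not None:
        j_slope = names.index(random_slope_col)
        re_scale = np.array([1.0, col_scale[j_slope]])
        exog_re = np.column_stack([np.ones(len(y)), x[:, j_slope]])
    else:
        re_scale = np.array([1.0])
        exog_re = np.ones((len(y), 1))

    def _run(free=None):
        # lbfgs is fastest on well-conditioned problems; fall back to
        # slower but more robust optimizers when it fails or stalls.
        last_err = None
        best = None
        for method in ("lbfgs", "bfgs", "powell"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, x, groups=subjects, exog_re=exog_re)
                try:
                    res = model.fit(reml=True, method=method, maxiter=500, free=free)
                except (np.linalg.LinAlgError, ValueError) as err:
                    last_err = err
                    continue
            if res.converged:
                return res
            if best is None:
                best = res
        if best is None:
            raise RuntimeError(f"mixed-model fit failed: {last_err}")
        return best

    res = _run()
    singular = False
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    eig = np.linalg.eigvalsh(cov_re)
    needs_refit = (not res.converged) or eig.min() < -1e-10 or (
        cov_re.shape[0] == 2 and eig.min() < 1e-12 * max(1.0, eig.max())
    )
    if needs_refit and cov_re.shape[0] == 2:
        free = MixedLMParams.from_components(
            fe_params=np.ones(x.shape[1]), cov_re=np.eye(2)
        )
        res2 = _run(free=free)
        if res2.converged or not res.converged:
            res = res2
            singular = True
            cov_re = np.atleast_2d(np.asarray(res.cov_re))

    params = pd.Series(
        np.asarray(res.fe_params, dtype=float) / col_scale, index=names
    )
    k = len(names)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k] / np.outer(col_scale, col_scale),
        index=names, columns=names,
    )
    cov_re = cov_re / np.outer(re_scale, re_scale)
    return (
        params, cov, cov_re, float(res.scale), bool(res.converged),
        singular, float(res.llf), False,
    )


def fit_rcr_region(
    table: pd.DataFrame, region: str, groups: str = "both"
) -> RCRFit:
    """Fit the random-intercept/random-slope RCR model for one region.

    ``groups="both"`` fits GMD ~ month + group + group:month + age +
    gender (HC and female as reference levels); ``groups="ad_only"``
    restricts to AD patients and fits GMD ~ month, giving the (beta0,
    beta1) pair consumed by the detection-interval statistic.
    """
    df = _first_scans(table)
    df = df[df["region"] == region]
    if df.empty:
        raise ValueError(f"no rows for region {region!r}")
    if groups == "ad_only":
        df = df[df["group"] == "AD"]
        if df.empty:
            raise ValueError("no AD rows for AD-only fit")
        design = pd.DataFrame(
            {"intercept": 1.0, "month": df["month"].to_numpy(dtype=float)}
        )
    elif groups == "both":
        if not {"AD", "HC"} <= set(df["group"]):
            raise ValueError("both groups are required for groups='both'")
        ad = (df["group"] == "AD").astype(float).to_numpy()
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "month": df["month"].to_numpy(dtype=float),
                "group_ad": ad,
                "month:group_ad": df["month"].to_numpy(dtype=float) * ad,
                "age": df["age"].to_numpy(dtype=float),
                "gender_m": (df["gender"] == "M").astype(float).to_numpy(),
            }
        )
        if design["gender_m"].nunique() == 1:
            design = design.drop(columns="gender_m")  # single-gender cohort
    else:
        raise ValueError("groups must be 'both' or 'ad_only'")

    y = df["gmd"].to_numpy(dtype=float)
    subjects = df["subject"].to_numpy()
    params, cov, cov_re, resid_var, converged, singular, llf, exact = _fit_lmm(
        y, design, subjects, random_slope_col="month"
    )
    return RCRFit(
        params=params, cov=cov, cov_re=cov_re, resid_var=resid_var,
        converged=converged, singular_refit=singular, loglik=llf,
        n_obs=len(y), n_subjects=int(pd.unique(subjects).size),
        exact=exact, groups_mode=groups,
    )


def group_percent_difference(
    fit: RCRFit, hc_slope_floor: float = 1e-8
) -> tuple[float, float | None]:
    """Express a both-groups RCR fit as study-style percentages.

    Returns ``(baseline_pct_lower, slope_pct_faster)``: the AD baseline
    deficit as a percent of the HC adjusted baseline mean, and the AD
    excess decline rate as a percent of the HC slope (positive = AD
    declines faster when both slopes are negative).  The slope percentage
    is ``None`` when the HC slope magnitude is below ``hc_slope_floor``.
    """
    if fit.groups_mode != "both":
        raise ValueError("percentage contrasts need a both-groups fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    b0 = float(fit.params["intercept"])
    if b0 <= 0:
        raise ValueError("HC adjusted baseline mean must be positive")
    baseline_pct = 100.0 * (-float(fit.params["group_ad"])) / b0
    slope_hc = float(fit.params["month"])
    slope_ad = slope_hc + float(fit.params["month:group_ad"])
    if abs(slope_hc) < hc_slope_floor:
        return baseline_pct, None
    slope_pct = 100.0 * (slope_ad - slope_hc) / slope_hc
    return baseline_pct, slope_pct


@dataclass(frozen=True)
class MMSETrendResult:
    ad_slope: float
    ad_ci: tuple[float, float]
    ad_p: float
    hc_slope: float
    hc_ci: tuple[float, float]
    hc_p: float
    intercept_diff_f: float
    intercept_diff_p: float
    slope_diff_f: float
    slope_diff_p: float
    fit: RCRFit = field(repr=False)


def _f_from_wald(est: float, se: float) -> tuple[float, float]:
    """Single-contrast Wald F (= z^2) and its p-value."""
    if se == 0.0:
        return (float("inf"), 0.0) if est != 0.0 else (0.0, 1.0)
    f = (est / se) ** 2
    return float(f), float(stats.chi2.sf(f, 1))


def mmse_trend(table: pd.DataFrame) -> MMSETrendResult:
    """RCR of MMSE on months since 1st MRI with group-specific intercepts
    and slopes (random intercept + slope per subject); group contrasts by
    Wald F-tests."""
    df = _first_scans(table)
    df = df.drop_duplicates(subset=["subject", "month"])
    df = df.dropna(subset=["mmse"])
    if df.empty:
        raise ValueError("no MMSE observations")
    if not {"AD", "HC"} <= set(df["group"]):
        raise ValueError("both groups are required")
    ad = (df["group"] == "AD").astype(float).to_numpy()
    month = df["month"].to_numpy(dtype=float)
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "month": month,
            "group_ad": ad,
            "month:group_ad": month * ad,
        }
    )
    y = df["mmse"].to_numpy(dtype=float)
    params, cov, cov_re, resid_var, converged, singular, llf, exact = _fit_lmm(
        y, design, df["subject"].to_numpy(), random_slope_col="month"
    )
    fit = RCRFit(
        params=params, cov=cov, cov_re=cov_re, resid_var=resid_var,
        converged=converged, singular_refit=singular, loglik=llf,
        n_obs=len(y), n_subjects=int(df["subject"].nunique()),
        exact=exact, groups_mode="both",
    )
    hc_slope, hc_ci, hc_p = fit.wald("month")
    ad_slope, ad_ci, ad_p = fit.contrast({"month": 1.0, "month:group_ad": 1.0})
    int_est, _, _ = fit.wald("group_ad")
    int_f, int_p = _f_from_wald(int_est, fit.se("group_ad"))
    slp_est, _, _ = fit.wald("month:group_ad")
    slp_f, slp_p = _f_from_wald(slp_est, fit.se("month:group_ad"))
    return MMSETrendResult(
        ad_slope=ad_slope, ad_ci=ad_ci, ad_p=ad_p,
        hc_slope=hc_slope, hc_ci=hc_ci, hc_p=hc_p,
        intercept_diff_f=int_f, intercept_diff_p=int_p,
        slope_diff_f=slp_f, slope_diff_p=slp_p, fit=fit,
    )


@dataclass(frozen=True)
class ChangeChangeResult:
    region: str
    ad_slope: float
    ad_ci: tuple[float, float]
    ad_p: float
    hc_slope: float
    hc_ci: tuple[float, float]
    hc_p: float
    diff: float
    diff_ci: tuple[float, float]
    diff_p: float
    fit: RCRFit = field(repr=False)


def change_change_rcr(table: pd.DataFrame, region: str) -> ChangeChangeResult:
    """RCR of longitudinal MMSE change on longitudinal GMD change.

    Per-subject changes from the 1st MRI are computed at every follow-up
    visit; the model has group-specific intercepts and slopes of
    delta-MMSE on delta-GMD with a per-subject random intercept.  Reports
    per-group slope tests and the between-group slope contrast.
    """
    df = _first_scans(table)
    df = df[df["region"] == region].dropna(subset=["mmse"])
    if df.empty:
        raise ValueError(f"no rows for region {region!r}")
    df = df.sort_values(["subject", "month"])
    base = df.groupby("subject").first()
    merged = df.merge(
        base[["gmd", "mmse"]].rename(columns={"gmd": "gmd0", "mmse": "mmse0"}),
        left_on="subject", right_index=True,
    )
    follow = merged[merged["month"] > merged.groupby("subject")["month"].transform("min")]
    if follow.empty:
        raise ValueError("no follow-up visits to compute changes from")
    dgmd = (follow["gmd"] - follow["gmd0"]).to_numpy(dtype=float)
    dmmse = (follow["mmse"] - follow["mmse0"]).to_numpy(dtype=float)
    if np.ptp(dgmd) == 0.0:
        raise ValueError("delta-GMD is constant: slope not identifiable")
    ad = (follow["group"] == "AD").astype(float).to_numpy()
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "dgmd": dgmd,
            "group_ad": ad,
            "dgmd:group_ad": dgmd * ad,
        }
    )
    params, cov, cov_re, resid_var, converged, singular, llf, exact = _fit_lmm(
        dmmse, design, follow["subject"].to_numpy(), random_slope_col=None
    )
    fit = RCRFit(
        params=params, cov=cov, cov_re=cov_re, resid_var=resid_var,
        converged=converged, singular_refit=singular, loglik=llf,
        n_obs=len(dmmse), n_subjects=int(follow["subject"].nunique()),
        exact=exact, groups_mode="both",
    )
    hc_slope, hc_ci, hc_p = fit.wald("dgmd")
    ad_slope, ad_ci, ad_p = fit.contrast({"dgmd": 1.0, "dgmd:group_ad": 1.0})
    diff, diff_ci, diff_p = fit.wald("dgmd:group_ad")
    return ChangeChangeResult(
        region=region,
        ad_slope=ad_slope, ad_ci=ad_ci, ad_p=ad_p,
        hc_slope=hc_slope, hc_ci=hc_ci, hc_p=hc_p,
        diff=diff, diff_ci=diff_ci, diff_p=diff_p, fit=fit,
    )
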