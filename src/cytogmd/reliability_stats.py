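"""Test-retest agreement between duplicate same-session scans.

Four complementary views of within-session measurement agreement for
standardized regional gray-matter density (GMD):

* the mean % change between the 1st and 2nd scans, modelled per region by
  a linear mixed model with a fixed HC mean, a fixed AD-HC difference and
  a per-subject random intercept (subjects contribute up to three
  replicate sessions);
* the one-way random-effects intraclass correlation (ICC) per group and
  region, with the exact F-based (Searle) confidence interval;
* the image intraclass correlation I2C2, a multivariate trace-ratio
  extension of the ICC across all regions simultaneously, with a
  subject-level bootstrap CI;
* a Bland-Altman analysis of the 2nd/1st scan ratio on the log scale
  (geometric mean ratio and 95% limits of agreement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .multiple_testing import apply_correction

__all__ = [
    "percent_change",
    "replicate_pairs",
    "within_session_change_model",
    "icc_oneway",
    "i2c2",
    "i2c2_bootstrap_ci",
    "bland_altman_ratio",
    "reliability_tables",
]


def percent_change(first: float, second: float) -> float:
    """Percent change of the 2nd measurement relative to the 1st:
    ``100 * (second - first) / first``."""
    if np.any(np.asarray(first) <= 0):
        raise ValueError("first measurement must be positive")
    return 100.0 * (np.asarray(second) - np.asarray(first)) / np.asarray(first)


def replicate_pairs(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extract within-session replicate pairs from a long cohort table.

    Returns one row per (subject, month, region) that has both replicate
    scans, with columns ``subject, group, month, region, first, second``.
    """
    required = {"subject", "group", "month", "replicate", "region", "gmd"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    wide = cohort.pivot_table(
        index=["subject", "group", "month", "region"],
        columns="replicate",
        values="gmd",
        aggfunc="first",
    )
    if 2 not in wide.columns:
        raise ValueError("no replicate scans found in the cohort table")
    wide = wide.dropna(subset=[1, 2])
    out = wide.reset_index().rename(columns={1: "first", 2: "second"})
    out.columns.name = None
    return out[["subject", "group", "month", "region", "first", "second"]]


@dataclass(frozen=True)
class WithinSessionResult:
    """Mixed-model summary of within-session % change for one region."""

    region: str
    hc_mean: float
    hc_ci: tuple[float, float]
    hc_p: float
    ad_mean: float
    ad_ci: tuple[float, float]
    ad_p: float
    diff: float  # AD - HC difference in mean % change
    diff_ci: tuple[float, float]
    diff_p: float
    n_sessions: int


def _wald(est: float, se: float, level: float = 0.95):
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
        return (est, est), p
    z = stats.norm.ppf(0.5 + level / 2.0)
    ci = (est - z * se, est + z * se)
    p = 2.0 * stats.norm.sf(abs(est) / se)
    return ci, p


def within_session_change_model(
    pairs: pd.DataFrame, region: str | None = None
) -> WithinSessionResult:
    """Estimate the mean within-session % change (HC) and the AD-HC
    difference with a random-intercept mixed model.

    ``pairs`` is the output of :func:`replicate_pairs`; if ``region`` is
    given the table is filtered to it first.  Each subject-session
    contributes one % change observation.
    """
    df = pairs if region is None else pairs[pairs["region"] == region]
    if df.empty:
        raise ValueError(f"no replicate pairs for region {region!r}")
    df = df.copy()
    df["pct"] = percent_change(df["first"].values, df["second"].values)
    groups = set(df["group"])
    if not {"AD", "HC"} <= groups:
        raise ValueError("both AD and HC groups are required")
    for g in ("AD", "HC"):
        if df.loc[df["group"] == g, "subject"].nunique() < 2:
            raise ValueError(f"need at least 2 subjects in group {g}")

    y = df["pct"].to_numpy()
    ad = (df["group"] == "AD").astype(float).to_numpy()
    x = np.column_stack([np.ones_like(ad), ad])

    # Degenerate (noise-free) data: % changes constant within group.
    beta_ols, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta_ols
    scale = max(1.0, float(np.abs(y).max()))
    if float(resid @ resid) < 1e-20 * scale**2:
        hc, diff = float(beta_ols[0]), float(beta_ols[1])
        hc_ci, hc_p = _wald(hc, 0.0)
        diff_ci, diff_p = _wald(diff, 0.0)
        ad_ci, ad_p = _wald(hc + diff, 0.0)
        return WithinSessionResult(
            region or "", hc, hc_ci, hc_p, hc + diff, ad_ci, ad_p,
            diff, diff_ci, diff_p, len(df)
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, x, groups=df["subject"].to_numpy())
        fit = model.fit(reml=True)
    beta = fit.fe_params
    cov = np.asarray(fit.cov_params())[:2, :2]
    hc, diff = float(beta[0]), float(beta[1])
    se_hc = float(np.sqrt(cov[0, 0]))
    se_diff = float(np.sqrt(cov[1, 1]))
    se_ad = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]))
    hc_ci, hc_p = _wald(hc, se_hc)
    diff_ci, diff_p = _wald(diff, se_diff)
    ad_ci, ad_p = _wald(hc + diff, se_ad)
    return WithinSessionResult(
        region or "", hc, hc_ci, hc_p, hc + diff, ad_ci, ad_p,
        diff, diff_ci, diff_p, len(df)
    )


def icc_oneway(
    pairs: np.ndarray | list, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """One-way random-effects ICC for replicate pairs, with the exact
    F-based confidence interval.

    ``pairs`` is an (n, k) array of replicate measurements per entity
    (k = 2 for duplicate scans).  The estimator is
    ``(MSB - MSW) / (MSB + (k-1) MSW)`` from the one-way ANOVA mean
    squares; the CI transforms exact F-distribution limits for
    ``F0 = MSB/MSW`` with (n-1, n(k-1)) degrees of freedom.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("pairs must be an (n, k>=2) array")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 entities for the ICC")
    subj_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * float(((subj_means - grand) ** 2).sum()) / (n - 1)
    msw = float(((x - subj_means[:, None]) ** 2).sum()) / (n * (k - 1))
    if msb == 0.0 and msw == 0.0:
        raise ValueError("zero total variance: ICC undefined")
    if msw == 0.0:
        return 1.0, (1.0, 1.0)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f0 = msb / msw
    a = 1.0 - level
    df1, df2 = n - 1, n * (k - 1)
    fl = f0 / stats.f.ppf(1 - a / 2, df1, df2)
    fu = f0 * stats.f.ppf(1 - a / 2, df2, df1)
    lower = (fl - 1) / (fl + k - 1)
    upper = (fu - 1) / (fu + k - 1)
    return float(icc), (float(lower), float(upper))


def _as_replicate_array(replicates) -> np.ndarray:
    """Coerce input to an (n_subjects, n_replicates, n_regions) array."""
    arr = np.asarray(replicates, dtype=float)
    if arr.ndim == 2:  # single region: (n, J)
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("replicates must be (subjects, replicates, regions)")
    return arr


def i2c2(replicates) -> float:
    """Image intraclass correlation coefficient (trace-ratio estimator).

    ``replicates`` has shape (n_subjects, n_replicates, n_regions).  The
    estimator is ``1 - tr(S_U) / tr(S_W)`` where ``tr(S_U)`` sums the
    per-region within-subject (replicate error) variances and ``tr(S_W)``
    sums the per-region total variances of the replicate-mean-centred
    data.  Reduces to the univariate variance ratio for one region.
    """
    x = _as_replicate_array(replicates)
    n, j, r = x.shape
    if n < 3 or j < 2:
        raise ValueError("need >=3 subjects with >=2 replicates each")
    # within-subject error variance per region (unbiased, pooled)
    subj_mean = x.mean(axis=1, keepdims=True)
    ss_within = ((x - subj_mean) ** 2).sum(axis=(0, 1))
    tr_u = float(ss_within.sum()) / (n * (j - 1))
    # total variance of replicate-index-demeaned data per region
    centred = x - x.mean(axis=0, keepdims=True)
    flat = centred.reshape(n * j, r)
    tr_w = float((flat**2).sum()) / (n * j - 1)
    if tr_w == 0.0:
        raise ValueError("zero total variance: I2C2 undefined")
    return 1.0 - tr_u / tr_w


def i2c2_bootstrap_ci(
    replicates, b: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[tuple[float, float], int]:
    """Percentile bootstrap CI for the I2C2, resampling subjects.

    Returns ``((lower, upper), n_degenerate)`` where degenerate resamples
    (zero total variance) are skipped and counted.
    """
    if b < 50:
        raise ValueError("need at least 50 bootstrap replicates")
    x = _as_replicate_array(replicates)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    estimates = []
    degenerate = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        try:
            estimates.append(i2c2(x[idx]))
        except ValueError:
            degenerate += 1
    if not estimates:
        raise ValueError("all bootstrap resamples degenerate")
    a = 1.0 - level
    lo, hi = np.quantile(estimates, [a / 2, 1 - a / 2])
    return (float(lo), float(hi)), degenerate


@dataclass(frozen=True)
class BlandAltmanResult:
    gmr: float
    limits: tuple[float, float]
    p_value: float
    n: int


def bland_altman_ratio(
    first, second, limit_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland-Altman agreement of replicate scans on the ratio scale.

    Works on log-ratios ``ln(second/first)``: the geometric mean ratio is
    ``exp(mean)``, the 95% limits of agreement ``exp(mean +/- 1.96 SD)``,
    and the p-value is a two-sided one-sample t-test of the log-ratios
    against zero (GMR = 1).
    """
    f = np.asarray(first, dtype=float)
    s = np.asarray(second, dtype=float)
    if np.any(f <= 0) or np.any(s <= 0):
        raise ValueError("Bland-Altman ratio analysis needs positive values")
    logr = np.log(s / f)
    mean = float(logr.mean())
    gmr = float(np.exp(mean))
    if logr.size >= 2:
        sd = float(logr.std(ddof=1))
        limits = (float(np.exp(mean - limit_multiplier * sd)),
                  float(np.exp(mean + limit_multiplier * sd)))
        if sd == 0.0:
            p = 1.0 if mean == 0.0 else 0.0
        else:
            p = float(stats.ttest_1samp(logr, 0.0).pvalue)
    else:
        limits = (float("nan"), float("nan"))
        p = float("nan")
    return BlandAltmanResult(gmr=gmr, limits=limits, p_value=p, n=int(logr.size))


def reliability_tables(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    bootstrap_b: int = 1000,
    seed: int = 0,
    method: str = "paper_stepdown",
) -> dict[str, pd.DataFrame]:
    """Full per-region test-retest report for a cohort table.

    Returns a dict with:

    * ``"pct_change_AD"`` / ``"pct_change_HC"`` — per-region group mean %
      change, 95% CI, p-value, step-down multiplicity threshold, reject;
    * ``"pct_change_diff"`` — the AD-HC differences with their own
      corrected family;
    * ``"icc"`` — per-region ICC and exact CI per group;
    * ``"i2c2"`` — I2C2 with bootstrap CI per group and combined;
    * ``"bland_altman"`` — per-region, per-group geometric mean ratio
      and limits of agreement.
    """
    pairs = replicate_pairs(cohort)
    regions = list(dict.fromkeys(cohort["region"]))

    ws_rows, icc_rows, ba_rows = [], [], []
    for region in regions:
        res = within_session_change_model(pairs, region)
        ws_rows.append(res)
        sub = pairs[pairs["region"] == region]
        row_icc: dict = {"region": region}
        for g in ("AD", "HC"):
            gsub = sub[sub["group"] == g]
            icc, (lo, hi) = icc_oneway(gsub[["first", "second"]].to_numpy())
            row_icc[f"icc_{g}"] = icc
            row_icc[f"icc_{g}_lower"] = lo
            row_icc[f"icc_{g}_upper"] = hi
            ba = bland_altman_ratio(gsub["first"].to_numpy(), gsub["second"].to_numpy())
            ba_rows.append(
                {"region": region, "group": g, "gmr": ba.gmr,
                 "loa_lower": ba.limits[0], "loa_upper": ba.limits[1],
                 "p": ba.p_value, "n": ba.n}
            )
        icc_rows.append(row_icc)

    out: dict[str, pd.DataFrame] = {}
    for key, attr in (("AD", "ad"), ("HC", "hc")):
        tab = pd.DataFrame(
            {
                "region": regions,
                "mean_pct_change": [getattr(r, f"{attr}_mean") for r in ws_rows],
                "ci_lower": [getattr(r, f"{attr}_ci")[0] for r in ws_rows],
                "ci_upper": [getattr(r, f"{attr}_ci")[1] for r in ws_rows],
                "p": [getattr(r, f"{attr}_p") for r in ws_rows],
            }
        )
        corr = apply_correction(
            pd.Series(tab["p"].values, index=tab["region"]), alpha, method
        ).table
        tab = tab.merge(corr[["region", "rank", "threshold", "reject"]], on="region")
        out[f"pct_change_{key}"] = tab

    diff_tab = pd.DataFrame(
        {
            "region": regions,
            "diff_pct_change": [r.diff for r in ws_rows],
            "ci_lower": [r.diff_ci[0] for r in ws_rows],
            "ci_upper": [r.diff_ci[1] for r in ws_rows],
            "p": [r.diff_p for r in ws_rows],
        }
    )
    corr = apply_correction(
        pd.Series(diff_tab["p"].values, index=diff_tab["region"]), alpha, method
    ).table
    out["pct_change_diff"] = diff_tab.merge(
        corr[["region", "rank", "threshold", "reject"]], on="region"
    )
    out["icc"] = pd.DataFrame(icc_rows)
    out["bland_altman"] = pd.DataFrame(ba_rows)

    # I2C2 per group and combined, over subject x replicate x region arrays
    i2c2_rows = []
    for label, sub in (
        ("AD", pairs[pairs["group"] == "AD"]),
        ("HC", pairs[pairs["group"] == "HC"]),
        ("combined", pairs),
    ):
        # one entity per subject-session, regions in stable order
        wide1 = sub.pivot_table(index=["subject", "month"], columns="region",
                                values="first")[regions]
        wide2 = sub.pivot_table(index=["subject", "month"], columns="region",
                                values="second")[regions]
        arr = np.stack([wide1.to_numpy(), wide2.to_numpy()], axis=1)
        est = i2c2(arr)
        (lo, hi), _ = i2c2_bootstrap_ci(arr, b=bootstrap_b, seed=seed)
        i2c2_rows.append({"group": label, "i2c2": est, "ci_lower": lo, "ci_upper": hi})
    out["i2c2"] = pd.DataFrame(i2c2_rows)
    return out
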