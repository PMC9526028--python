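"""Criterion II: linear model of clustering on land-cover gradients and
green-space type, estimated-marginal-mean contrasts, collinearity
screening, and Moran's I residual diagnostics.

The model is ``ses_mfd ~ percent open green + percent impervious +
green-space type`` (treatment coding). Covariates enter on the percent
scale (raw proportions x 100) so coefficients are per percentage point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ecofilter.data_model import SiteTable


@dataclass
class DesignMatrix:
    """OLS design with bookkeeping for factor levels and covariates."""

    X: np.ndarray
    columns: list[str]
    site_ids: list[str]
    factor: str
    factor_levels: list[str]          # observed levels, reference first
    factor_of_site: dict[str, str]
    covariate_means: dict[str, float]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class LinearModelFit:
    design: DesignMatrix
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    resid: np.ndarray
    fittedvalues: np.ndarray
    cov_params: np.ndarray
    sigma2: float

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "t": self.tvalues,
             "p": self.pvalues},
            index=self.design.columns,
        )


@dataclass
class EmmContrastTable:
    emmeans: pd.DataFrame    # level, emmean, se
    contrasts: pd.DataFrame  # contrast, estimate, se, t_ratio, df, p_adj
    adjust: str


@dataclass
class MoranResult:
    observed_i: float
    expected_i: float
    variance: float
    z: float
    p_two_tailed: float
    weights_descriptor: str
    p_permutation: float | None = None


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    threshold: float
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def build_design(
    sites: SiteTable,
    scale: int,
    factor_reference: str = "community_garden",
    percent: bool = True,
    covariates: tuple[str, ...] = ("open_green", "impervious"),
) -> DesignMatrix:
    """Intercept + covariates + treatment-coded green-space dummies."""
    cov = sites.covariates(scale)[list(covariates)]
    if percent:
        cov = cov * 100.0
    ugs = sites.data["ugs_type"].astype(str)
    observed = [lv for lv in ugs.unique()]
    if factor_reference in observed:
        levels = [factor_reference] + sorted(
            lv for lv in observed if lv != factor_reference)
    else:
        levels = sorted(observed)
        warnings.warn(
            f"reference level {factor_reference!r} not observed; using "
            f"{levels[0]!r}", stacklevel=2)
    if len(levels) < 2:
        warnings.warn("single green-space level observed; no dummies",
                      stacklevel=2)
    cols = ["intercept"] + list(covariates) + [f"ugs[{lv}]" for lv in levels[1:]]
    X = np.column_stack(
        [np.ones(len(cov))]
        + [cov[c].to_numpy() for c in covariates]
        + [(ugs == lv).to_numpy(dtype=float) for lv in levels[1:]]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return DesignMatrix(
        X=X,
        columns=cols,
        site_ids=list(sites.site_ids),
        factor="ugs_type",
        factor_levels=levels,
        factor_of_site=dict(zip(sites.site_ids, ugs)),
        covariate_means={c: float(cov[c].mean()) for c in covariates},
    )


def fit_ols(design: DesignMatrix, response: np.ndarray | pd.Series) -> LinearModelFit:
    """Ordinary least squares with classical t tests on n - p df."""
    y = np.asarray(response, dtype=float)
    X = design.X
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    import statsmodels.api as sm

    try:
        res = sm.OLS(y, X).fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(f"singular normal equations: {exc}") from exc
    return LinearModelFit(
        design=design,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        df_resid=int(res.df_resid),
        resid=np.asarray(res.resid),
        fittedvalues=np.asarray(res.fittedvalues),
        cov_params=np.asarray(res.cov_params()),
        sigma2=float(res.mse_resid),
    )


def _level_row(fit: LinearModelFit, level: str) -> np.ndarray:
    """Prediction row for one factor level at covariate means."""
    d = fit.design
    row = np.zeros(d.p)
    row[0] = 1.0
    for j, col in enumerate(d.columns):
        if col in d.covariate_means:
            row[j] = d.covariate_means[col]
        elif col == f"ugs[{level}]":
            row[j] = 1.0
    return row


def emm_pairwise(
    fit: LinearModelFit,
    factor: str = "ugs_type",
    covariates_at: str = "mean",
    adjust: str = "tukey",
) -> EmmContrastTable:
    """Estimated marginal means and pairwise contrasts for the factor.

    EMM of a level is the model prediction with covariates held at their
    observed means. Contrast SEs come from the coefficient covariance;
    the Tukey adjustment uses the studentized-range distribution with
    k = number of levels on the residual df.
    """
    d = fit.design
    if factor != d.factor:
        raise ValueError(f"factor {factor!r} not in model (has {d.factor!r})")
    if covariates_at != "mean":
        raise ValueError("only covariates_at='mean' is supported")
    levels = d.factor_levels
    rows = {lv: _level_row(fit, lv) for lv in levels}
    emm = {lv: float(rows[lv] @ fit.params) for lv in levels}
    emm_se = {lv: float(np.sqrt(rows[lv] @ fit.cov_params @ rows[lv]))
              for lv in levels}
    emmeans = pd.DataFrame(
        {"level": levels, "emmean": [emm[lv] for lv in levels],
         "se": [emm_se[lv] for lv in levels]}
    )
    k = len(levels)
    recs = []
    for a, b in combinations(levels, 2):
        c = rows[a] - rows[b]
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        t = est / se
        p_raw = float(2 * stats.t.sf(abs(t), fit.df_resid))
        if adjust == "tukey" and k > 2:
            p_adj = float(stats.studentized_range.sf(
                abs(t) * np.sqrt(2.0), k, fit.df_resid))
        elif adjust == "bonferroni":
            p_adj = min(1.0, p_raw * k * (k - 1) / 2)
        else:  # none, or tukey with k == 2 (q = t*sqrt(2) identity)
            p_adj = p_raw
        recs.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "t_ratio": t, "df": fit.df_resid, "p_adj": p_adj,
                     "p_raw": p_raw})
    return EmmContrastTable(emmeans=emmeans, contrasts=pd.DataFrame(recs),
                            adjust=adjust)


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    n_perm: int = 0,
    rng: np.random.Generator | int | None = None,
) -> MoranResult:
    """Moran's I with the normality-assumption variance and z test.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with centered values
    z; E[I] = -1/(n-1). Optionally a permutation p-value over n_perm
    random relabelings.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if w.shape != (n, n):
        raise ValueError("weights must be n x n")
    if np.any(np.diag(w) != 0):
        raise ValueError("weight matrix must have zero diagonal")
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("all-zero weight matrix")
    z = x - x.mean()
    m2 = float(z @ z)
    if m2 == 0:
        raise ValueError("zero variance in values")

    def _stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ w @ zv) / (zv @ zv))

    i_obs = _stat(z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = ((n * n * s1 - n * s2 + 3 * s0 * s0)
           / ((n * n - 1) * s0 * s0)) - e_i * e_i
    if var > 0:
        zscore = (i_obs - e_i) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(zscore)))
    else:  # e.g. complete-graph weights: I is degenerate under normality
        zscore = float("nan")
        p = float("nan")
    p_perm = None
    if n_perm > 0:
        gen = np.random.default_rng(rng)
        count = 0
        for _ in range(n_perm):
            perm = _stat(gen.permutation(z))
            if abs(perm - e_i) >= abs(i_obs - e_i):
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return MoranResult(i_obs, e_i, float(var), float(zscore), p,
                       "user-supplied", p_perm)


def knn_weights(coords: np.ndarray, k: int = 8,
                row_standardize: bool = True) -> np.ndarray:
    """Symmetric-in-support k-nearest-neighbour binary weights."""
    xy = np.asarray(coords, dtype=float)
    n = len(xy)
    if k >= n:
        raise ValueError("k must be < number of sites")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros((n, n))
    nbrs = np.argsort(d2, axis=1)[:, :k]
    for i in range(n):
        w[i, nbrs[i]] = 1.0
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    return w


def idw_weights(coords: np.ndarray, power: float = 1.0,
                row_standardize: bool = True) -> np.ndarray:
    """Inverse-distance weights, optionally row-standardized."""
    xy = np.asarray(coords, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d ** power
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    return w


def collinearity_screen(
    sites: SiteTable,
    scale: int,
    threshold: float = 0.7,
    drop: str = "closed_green",
) -> CollinearityReport:
    """Pearson correlations among candidate covariates; flag |r| >= threshold.

    When any pair involving ``drop`` is flagged, that variable enters the
    dropped set (the study removed closed green cover for its collinearity
    with impervious surface).
    """
    cov = sites.covariates(scale)
    corr = cov.corr(method="pearson")
    flagged = []
    dropped: list[str] = []
    for a, b in combinations(cov.columns, 2):
        r = float(corr.loc[a, b])
        if abs(r) >= threshold:
            flagged.append((a, b, r))
            if drop in (a, b) and drop not in dropped:
                dropped.append(drop)
    return CollinearityReport(correlations=corr, threshold=threshold,
                              flagged_pairs=flagged, dropped=dropped)
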