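"""Comparison statistics for two-group, two-visit intervention designs.

Covers the study-style toolkit: paired and unpaired t tests with 95%
confidence intervals, Pearson chi-square on contingency tables (no
continuity correction by default), ANCOVA-adjusted group means from an
ordinary least-squares fit, and paired-t power / sample size from the
noncentral t distribution. No multiple-testing adjustment is applied
anywhere; reports annotate how many tests were run instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class TTestResult:
    estimate: float  # mean (paired: of differences) or mean difference a-b
    ci_low: float
    ci_high: float
    t_statistic: float
    df: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AncovaResult:
    adjusted_means: dict[str, float]
    standard_errors: dict[str, float]
    p_value: float  # group-effect test
    covariate_names: list[str] = field(default_factory=list)
    n: int = 0


def paired_t(differences: np.ndarray, confidence: float = 0.95) -> TTestResult:
    """Two-sided one-sample t test on paired differences, with CI.

    CI is mean +/- t_{(1+conf)/2, n-1} * SE. Zero-variance input yields a
    degenerate result (p undefined as NaN) rather than an exception.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValueError(f"paired t test needs >= 2 differences, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return TTestResult(mean, mean, mean, float("nan"), df, float("nan"), n,
                           degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df)
    tstat = mean / se
    p = 2 * stats.t.sf(abs(tstat), df)
    return TTestResult(mean, mean - tcrit * se, mean + tcrit * se,
                       float(tstat), df, float(p), n)


def unpaired_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    variance_mode: str = "pooled",
    confidence: float = 0.95,
) -> TTestResult:
    """Two-sample t test of mean(a) - mean(b).

    ``pooled`` is the classical equal-variance Student t (default);
    ``welch`` uses the Satterthwaite degrees of freedom.
    """
    if variance_mode not in ("pooled", "welch"):
        raise ValueError(f"variance_mode must be 'pooled' or 'welch', got {variance_mode!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 observations")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return TTestResult(diff, diff, diff, float("nan"), na + nb - 2,
                           float("nan"), na + nb, degenerate=True)
    if variance_mode == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    tstat = diff / se
    p = 2 * stats.t.sf(abs(tstat), df)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df)
    return TTestResult(diff, diff - tcrit * se, diff + tcrit * se,
                       float(tstat), float(df), float(p), na + nb)


def pearson_chi_square(
    table: np.ndarray, yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts are the product of marginals over the total;
    df = (r-1)(c-1). No continuity correction unless ``yates`` (2x2
    only).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0):
        raise ValueError(f"empty row(s) at index {np.flatnonzero(row == 0).tolist()}")
    if np.any(col == 0):
        raise ValueError(f"empty column(s) at index {np.flatnonzero(col == 0).tolist()}")
    total = obs.sum()
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(chi2, df, float(stats.chi2.sf(chi2, df)))


def ancova_adjusted_means(
    outcome: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> AncovaResult:
    """Covariate-adjusted group means from a least-squares fit.

    Fits ``outcome ~ group indicators + covariates`` by OLS after
    listwise deletion of incomplete rows. The adjusted mean of each
    group is the model prediction at that group with every covariate at
    its grand mean over the analysis sample; standard errors come from
    the coefficient covariance. The group p-value is the (two-group)
    group-coefficient t test, equivalent to the one-way F test here.
    """
    y = np.asarray(outcome, dtype=float)
    g = pd.Series(group).astype(str).to_numpy()
    if covariates is None or len(getattr(covariates, "columns", [])) == 0:
        X_cov = pd.DataFrame(index=range(y.size))
        cov_names: list[str] = []
    else:
        X_cov = covariates.reset_index(drop=True).astype(float)
        cov_names = list(X_cov.columns)
    keep = ~np.isnan(y)
    if cov_names:
        keep &= ~X_cov.isna().any(axis=1).to_numpy()
    y, g, X_cov = y[keep], g[keep], X_cov.loc[keep].reset_index(drop=True)
    levels = sorted(set(g))
    if len(levels) != 2:
        raise ValueError(f"ANCOVA here expects exactly 2 groups, got {levels}")
    constant = [c for c in cov_names if X_cov[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant covariate(s) {constant} from the ANCOVA design",
            stacklevel=2,
        )
        cov_names = [c for c in cov_names if c not in constant]
        X_cov = X_cov[cov_names]
    indicator = (g == levels[1]).astype(float)  # treatment coding vs levels[0]
    design = pd.DataFrame({"const": 1.0, "group": indicator})
    for c in cov_names:
        design[c] = X_cov[c].to_numpy()
    if y.size <= design.shape[1]:
        raise ValueError("not enough observations for the requested model")
    # column-normalized rank check so disparate covariate scales do not
    # masquerade as collinearity
    mat = design.to_numpy()
    rank = np.linalg.matrix_rank(mat / np.linalg.norm(mat, axis=0))
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design: columns {list(design.columns)} are collinear"
        )
    fit = sm.OLS(y, design).fit()
    cov_beta = fit.cov_params().to_numpy()
    grand_means = {c: float(X_cov[c].mean()) for c in cov_names}
    adjusted: dict[str, float] = {}
    ses: dict[str, float] = {}
    for level, ind in zip(levels, (0.0, 1.0)):
        contrast = np.array([1.0, ind] + [grand_means[c] for c in cov_names])
        adjusted[level] = float(contrast @ fit.params.to_numpy())
        ses[level] = float(np.sqrt(contrast @ cov_beta @ contrast))
    return AncovaResult(
        adjusted_means=adjusted,
        standard_errors=ses,
        p_value=float(fit.pvalues["group"]),
        covariate_names=cov_names,
        n=int(y.size),
    )


def paired_t_power(n: int, dz: float, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t test at standardized effect dz."""
    if n < 2:
        return 0.0
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    nc = dz * np.sqrt(n)
    return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def paired_t_sample_size(
    dz: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 10**6
) -> int:
    """Smallest n >= 2 whose two-sided paired-t power reaches the target.

    Power is evaluated from the noncentral t distribution with
    noncentrality dz * sqrt(n); n is scanned upward (power is monotone
    in n).
    """
    if not dz > 0:
        raise ValueError(f"standardized effect dz must be > 0, got {dz}")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    # bracket by doubling from a normal-approximation start, then bisect
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    lo = 2
    hi = min(max(2, int(np.ceil((z / dz) ** 2))), n_max)
    while paired_t_power(hi, dz, alpha) < power:
        if hi >= n_max:
            raise ValueError(f"target power {power} not reachable within n <= {n_max}")
        hi = min(2 * hi, n_max)
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_t_power(mid, dz, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo
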