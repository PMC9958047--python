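"""Statistical layer: OLS with AIC model ladders, segmented (breakpoint)
regression, variance-homogeneity tests, thermal-variability summaries,
growth-rate extraction and one-way ANOVA.

All estimators are implemented directly from the textbook formulas; SciPy is
used only for reference distributions (F) and scalar optimisation.  AIC uses
the full Gaussian log-likelihood (including the ``n log 2*pi`` constant and
the variance as a fitted parameter) so that ladders are directly comparable
with mainstream statistical software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import f as f_dist


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Simple or multiple OLS fit summary."""

    slope: float            # first-covariate slope (NaN for intercept-only)
    intercept: float
    r2: float
    f: float
    df: tuple[int, int]     # (treatment, residual)
    p: float
    aic: float
    n: int
    rss: float
    coefs: tuple[float, ...] = field(default=())


@dataclass(frozen=True)
class ModelFit:
    """One rung of an AIC model ladder."""

    terms: tuple[str, ...]
    df: tuple[int, int]
    r2: float
    aic: float
    best: bool


@dataclass(frozen=True)
class SegmentedFit:
    breakpoint: float
    slope_before: float
    slope_after: float
    intercept: float
    r2: float
    p: float                # improvement over the single-line model
    rss: float
    converged: bool


@dataclass(frozen=True)
class VariabilitySummary:
    mat: float              # mean of the series
    delta_t: float          # max - min
    bin_freq: tuple[float, ...]   # percent of time per bin, sums to 100
    label: str              # HTV / ITV / LTV


@dataclass(frozen=True)
class GrowthResult:
    rate: float | None      # per hour; None when no growth
    grew: bool
    od_threshold: float
    max_od: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _gaussian_aic(rss: float, n: int, n_coef: int) -> float:
    """AIC of a Gaussian OLS fit; parameter count includes the variance."""
    rss = max(rss, 1e-300)  # guard exact fits
    loglik = -0.5 * n * (np.log(2.0 * np.pi) + np.log(rss / n) + 1.0)
    return -2.0 * loglik + 2.0 * (n_coef + 1)


def _ols(x_design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(x_design, y, rcond=None)
    resid = y - x_design @ coef
    return coef, float(resid @ resid)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def ols_regress(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple linear regression of ``y`` on ``x`` with F-test and AIC.

    Raises ``ValueError`` for fewer than 3 points or a constant ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")

    design = np.column_stack([np.ones(n), x])
    coef, rss = _ols(design, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    df = (1, n - 2)
    if rss <= 0 or tss <= rss:
        # exact or better-than-exact fit within fp noise
        rss = max(rss, 0.0)
    fstat = np.inf if rss == 0 else ((tss - rss) / 1.0) / (rss / df[1])
    p = 0.0 if not np.isfinite(fstat) else float(f_dist.sf(fstat, *df))
    return RegressionResult(
        slope=float(coef[1]), intercept=float(coef[0]), r2=float(np.clip(r2, 0, 1)),
        f=float(fstat), df=df, p=p, aic=_gaussian_aic(rss, n, 2), n=n, rss=rss,
        coefs=tuple(float(c) for c in coef),
    )


def multiple_regress(X: np.ndarray, y: np.ndarray,
                     terms: tuple[str, ...]) -> ModelFit:
    """OLS with an intercept plus the columns of ``X``; one ladder rung."""
    y = np.asarray(y, dtype=float)
    n = y.size
    k = 0 if X is None else X.shape[1]
    design = np.ones((n, 1)) if k == 0 else np.column_stack([np.ones(n), X])
    if k > 0:
        cond = np.linalg.cond(design)
        if cond > 1e8:
            warnings.warn(f"collinear covariates (condition number {cond:.3g})")
    coef, rss = _ols(design, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = np.nan if k == 0 else (1.0 if tss == 0 else 1.0 - rss / tss)
    df = (max(k, 1), n - 1 - k)
    return ModelFit(terms=terms, df=df, r2=r2,
                    aic=_gaussian_aic(rss, n, k + 1), best=False)


def compare_models(frame, response: str,
                   covariates: Sequence[str] = ("MAT", "pH", "salinity"),
                   ) -> list[ModelFit]:
    """Fit every subset of ``covariates`` (intercept-only through full model)
    and return the ladder ordered by subset size, lowest AIC flagged best.
    """
    y = np.asarray(frame[response], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    cols = {c: np.asarray(frame[c], dtype=float) for c in covariates}
    for c, v in cols.items():
        if np.any(~np.isfinite(v)):
            raise ValueError(f"covariate {c!r} contains non-finite values")

    ladder: list[ModelFit] = []
    for size in range(len(covariates) + 1):
        for subset in combinations(covariates, size):
            X = None if not subset else np.column_stack([cols[c] for c in subset])
            ladder.append(multiple_regress(X, y, subset))
    best_i = int(np.argmin([m.aic for m in ladder]))
    return [ModelFit(m.terms, m.df, m.r2, m.aic, i == best_i)
            for i, m in enumerate(ladder)]


def _segmented_rss(x: np.ndarray, y: np.ndarray, psi: float
                   ) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    coef, rss = _ols(design, y)
    return rss, coef


def segmented_regress(x: Sequence[float], y: Sequence[float],
                      min_per_segment: int = 3) -> SegmentedFit:
    """Continuous two-segment least squares with one free breakpoint.

    The breakpoint is profiled over the unique interior x-values (1st-99th
    percentile, at least ``min_per_segment`` points on each side) and refined
    by bounded scalar minimisation between the neighbouring candidates.  Ties
    on RSS resolve to the smaller breakpoint.  The improvement p-value is an
    F-test of the segmented model (2 extra parameters) against a single line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 7 or y.size != n:
        raise ValueError("need at least 7 paired observations")

    xs = np.unique(x)
    lo, hi = np.percentile(x, [1, 99])
    cands = [float(c) for c in xs
             if lo <= c <= hi
             and np.sum(x <= c) >= min_per_segment
             and np.sum(x > c) >= min_per_segment]
    if not cands:
        raise ValueError("no interior breakpoint candidates")

    rss_grid = np.array([_segmented_rss(x, y, c)[0] for c in cands])
    best = int(np.argmin(rss_grid))  # argmin takes the first (smallest) tie

    # refine between the candidates bracketing the grid optimum
    left = cands[best - 1] if best > 0 else cands[best]
    right = cands[best + 1] if best < len(cands) - 1 else cands[best]
    psi = cands[best]
    if right > left:
        res = optimize.minimize_scalar(
            lambda p: _segmented_rss(x, y, p)[0],
            bounds=(left, right), method="bounded",
            options={"xatol": 1e-8})
        if res.fun <= rss_grid[best] + 1e-12:
            psi = float(res.x)

    rss_seg, coef = _segmented_rss(x, y, psi)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss_seg / tss

    lin = np.column_stack([np.ones_like(x), x])
    _, rss_lin = _ols(lin, y)
    df2 = n - 4  # intercept, slope, slope change, breakpoint
    if rss_seg <= 1e-12 * max(tss, 1.0):
        p = 0.0
    else:
        fstat = ((rss_lin - rss_seg) / 2.0) / (rss_seg / df2)
        p = float(f_dist.sf(max(fstat, 0.0), 2, df2))
    return SegmentedFit(
        breakpoint=float(psi),
        slope_before=float(coef[1]),
        slope_after=float(coef[1] + coef[2]),
        intercept=float(coef[0]),
        r2=float(np.clip(r2, 0.0, 1.0)),
        p=p, rss=rss_seg, converged=True,
    )


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def anova_oneway(groups: Sequence[Sequence[float]]
                 ) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA.  Returns (F, (df_between, df_within), p)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least two observations")
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    grand = np.concatenate(gs).mean()
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, gs)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df = (k - 1, N - k)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df, 1.0
        return np.inf, df, 0.0
    fstat = (ssb / df[0]) / (ssw / df[1])
    return float(fstat), df, float(f_dist.sf(fstat, *df))


def levene_test(groups: Sequence[Sequence[float]], center: str = "median"
                ) -> tuple[float, tuple[int, int], float]:
    """Variance-homogeneity test: one-way ANOVA on absolute deviations from
    each group's center (median by default, i.e. Brown-Forsythe)."""
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >=2 groups with >=2 observations each")
    cfun = np.median if center == "median" else np.mean
    z = [np.abs(g - cfun(g)) for g in gs]
    return anova_oneway(z)


# ---------------------------------------------------------------------------
# thermal variability and growth
# ---------------------------------------------------------------------------

#: delta-T thresholds (max - min, degC) separating variability classes
VARIABILITY_THRESHOLDS = {"HTV": 10.0, "ITV": 7.5}


def variability_summary(series: Sequence[float],
                        bins: tuple[float, float] = (28.0, 31.0)
                        ) -> VariabilitySummary:
    """Summarise a temperature series: mean (MAT), range, and percent of time
    in the closed-open bins (-inf, lo), [lo, hi), [hi, inf)."""
    t = np.asarray(series, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    lo, hi = bins
    n = t.size
    freqs = (
        100.0 * np.sum(t < lo) / n,
        100.0 * np.sum((t >= lo) & (t < hi)) / n,
        100.0 * np.sum(t >= hi) / n,
    )
    dt = float(np.ptp(t))
    if dt >= VARIABILITY_THRESHOLDS["HTV"]:
        label = "HTV"
    elif dt >= VARIABILITY_THRESHOLDS["ITV"]:
        label = "ITV"
    else:
        label = "LTV"
    return VariabilitySummary(mat=float(t.mean()), delta_t=dt,
                              bin_freq=freqs, label=label)


def growth_rate(time_h: Sequence[float], od: Sequence[float],
                threshold: float = 0.15, window: int = 5) -> GrowthResult:
    """Growth rate from an OD600 time series.

    ODs are normalised to the initial inoculum; wells never reaching
    ``threshold`` raw OD are classified no-growth.  The rate is the maximum
    sliding-window slope of log(OD) in per-hour units.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od, dtype=float)
    if t.size < 3 or od.size != t.size:
        raise ValueError("need at least 3 paired time points")
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    max_od = float(od.max())
    if max_od < threshold:
        return GrowthResult(rate=None, grew=False, od_threshold=threshold,
                            max_od=max_od)
    log_od = np.log(od / od[0])
    w = min(window, t.size)
    best = -np.inf
    for i in range(t.size - w + 1):
        ts, ys = t[i:i + w], log_od[i:i + w]
        denom = np.sum((ts - ts.mean()) ** 2)
        if denom == 0:
            continue
        slope = np.sum((ts - ts.mean()) * (ys - ys.mean())) / denom
        best = max(best, slope)
    return GrowthResult(rate=float(best), grew=True, od_threshold=threshold,
                        max_od=max_od)
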