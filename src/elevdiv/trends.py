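"""Elevational trend fitting: linear, one-breakpoint segmented, Davies test.

Each metric (observed or SES) is regressed on elevation, taken as the lower
limit of each band.  A broken-line model with at most one breakpoint is
estimated by iterative linearisation: fit

    y ~ b0 + b1·x + beta·(x − psi)+ − gamma·I(x > psi)

by least squares and update psi by gamma_hat / beta_hat until the step is
negligible.  Whether the two slopes genuinely differ is decided by the
Davies test — the best difference-in-slope Wald statistic over a grid of
candidate breakpoints, corrected for the breakpoint being present only
under the alternative.  If the Davies test is not significant at p < 0.05
the relationship is reported as linear: that gate, and nothing else, is the
model-selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LinearFit", "SegmentedFit", "fit_linear", "fit_segmented", "davies_test",
           "select_and_report", "trends_table"]

ALPHA = 0.05


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    t_slope: float
    p_slope: float
    r2: float
    n: int


@dataclass
class SegmentedFit:
    """One-breakpoint broken-line fit plus the Davies-gated model choice."""

    selected_model: str  # 'linear' or 'segmented'
    slope1: float
    slope2: float | None
    psi: float | None
    t_slope1: float
    t_slope2: float | None
    r2: float
    davies_p: float
    n: int
    converged: bool = True
    linear: LinearFit | None = field(default=None, repr=False)


def _clean(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    return x[keep], y[keep], dropped


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares of y on x with slope t-statistic and R²."""
    x, y, _ = _clean(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else 0.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        t_slope=float(t),
        p_slope=float(res.pvalue),
        r2=float(res.rvalue**2),
        n=len(x),
    )


def _segmented_design(x: np.ndarray, psi: float) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x), x, np.clip(x - psi, 0.0, None), -(x > psi).astype(float)]
    )


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients, covariance and residual sum of squares."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    dof = len(y) - design.shape[1]
    xtx_inv = np.linalg.pinv(design.T @ design)
    sigma2 = rss / dof if dof > 0 else np.nan
    return beta, sigma2 * xtx_inv, rss


def fit_segmented(x, y, psi0: float | None = None, tol: float = 1e-6,
                  max_iter: int = 100) -> SegmentedFit:
    """Iteratively linearised one-breakpoint fit.

    The breakpoint is kept strictly inside [2nd smallest, 2nd largest] x so
    both segments retain at least two points.  On non-convergence the linear
    fit is returned with ``converged=False``.  The per-segment slope
    t-statistics come from the linearised fit's covariance (slope2 =
    slope1 + difference-in-slope).
    """
    x, y, _ = _clean(x, y)
    if len(x) < 5:
        raise ValueError("need at least 5 finite points for a segmented fit")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; segmented fit undefined")
    order = np.argsort(x)
    xs = x[order]
    lo, hi = xs[1], xs[-2]
    if not lo < hi:
        raise ValueError("x values too degenerate for an interior breakpoint")
    psi = float(np.median(x)) if psi0 is None else float(np.clip(psi0, lo, hi))
    span = xs[-1] - xs[0]
    converged = False
    for _ in range(max_iter):
        design = _segmented_design(x, psi)
        beta, cov, _ = _ols(design, y)
        b_diff = beta[2]
        if abs(b_diff) < 1e-12:
            break
        step = beta[3] / b_diff
        psi_new = float(np.clip(psi + step, lo, hi))
        if abs(psi_new - psi) < tol * span:
            psi = psi_new
            converged = True
            break
        psi = psi_new

    lin = fit_linear(x, y)
    if not converged:
        return SegmentedFit(
            selected_model="linear", slope1=lin.slope, slope2=None, psi=None,
            t_slope1=lin.t_slope, t_slope2=None, r2=lin.r2, davies_p=float("nan"),
            n=len(x), converged=False, linear=lin,
        )
    # final fit without the indicator term (gamma -> 0 at convergence)
    design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    beta, cov, rss = _ols(design, y)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    slope1 = float(beta[1])
    slope2 = float(beta[1] + beta[2])
    se1 = float(np.sqrt(max(cov[1, 1], 0.0)))
    se2 = float(np.sqrt(max(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2], 0.0)))
    t1 = slope1 / se1 if se1 > 0 else float("inf") * np.sign(slope1 or 1.0)
    t2 = slope2 / se2 if se2 > 0 else float("inf") * np.sign(slope2 or 1.0)
    return SegmentedFit(
        selected_model="segmented", slope1=slope1, slope2=slope2, psi=psi,
        t_slope1=t1, t_slope2=t2, r2=float(np.clip(r2, 0.0, 1.0)),
        davies_p=float("nan"), n=len(x), converged=True, linear=lin,
    )


def davies_test(x, y, grid: np.ndarray | None = None) -> float:
    """Davies' test for a difference in slopes at an unknown breakpoint.

    Evaluates the Wald statistic of the (x − psi)+ term at each candidate
    breakpoint (default: the interior observed x values), takes the most
    extreme, and applies Davies' upper bound for a nuisance parameter that
    exists only under the alternative:

        p = 2·P(t_df > M) + V·(1 + M²/df)^(−(df−1)/2) / sqrt(8·pi),

    with M the largest |statistic|, V the total variation of the statistic
    across the grid and df the residual degrees of freedom; p is capped
    at 1.  The bound is conservative, so the type-I rate stays at or below
    the nominal level.
    """
    x, y, _ = _clean(x, y)
    if len(x) < 5:
        raise ValueError("need at least 5 finite points for the Davies test")
    if grid is None:
        interior = np.unique(np.sort(x))[1:-1]
        grid = interior
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 3:
        warnings.warn("fewer than 3 interior candidate breakpoints; p = 1", stacklevel=2)
        return 1.0
    if np.ptp(y) == 0:
        return 1.0
    ts = np.empty(len(grid))
    for i, psi in enumerate(grid):
        design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        beta, cov, _ = _ols(design, y)
        se = np.sqrt(max(cov[2, 2], 0.0))
        ts[i] = beta[2] / se if se > 0 else 0.0
    m = float(np.max(np.abs(ts)))
    v = float(np.sum(np.abs(np.diff(ts))))
    df = len(x) - 3
    # t-process version of the bound: the Gaussian kernel exp(-M²/2) becomes
    # the t-density kernel (1 + M²/df)^(-(df-1)/2)
    p = 2.0 * stats.t.sf(m, df) + v * (1.0 + m * m / df) ** (-0.5 * (df - 1)) / np.sqrt(
        8.0 * np.pi
    )
    return float(min(p, 1.0))


def select_and_report(x, y, psi0: float | None = None) -> SegmentedFit:
    """Davies-gated model choice: segmented iff Davies p < 0.05, else linear."""
    x, y, _ = _clean(x, y)
    lin = fit_linear(x, y)
    if len(x) < 5:
        return SegmentedFit(
            selected_model="linear", slope1=lin.slope, slope2=None, psi=None,
            t_slope1=lin.t_slope, t_slope2=None, r2=lin.r2, davies_p=float("nan"),
            n=len(x), linear=lin,
        )
    p = davies_test(x, y)
    if p < ALPHA:
        fit = fit_segmented(x, y, psi0=psi0)
        fit.davies_p = p
        if fit.converged:
            return fit
    return SegmentedFit(
        selected_model="linear", slope1=lin.slope, slope2=None, psi=None,
        t_slope1=lin.t_slope, t_slope2=None, r2=lin.r2, davies_p=p,
        n=len(x), linear=lin,
    )


def trends_table(
    metric_frames: pd.DataFrame,
    elevations: dict[str, float],
    value_columns: list[str],
) -> pd.DataFrame:
    """Fit the Davies-gated model for every metric column × trait set.

    ``metric_frames`` is tidy with columns band, trait_set and the metric
    value columns; ``elevations`` maps band label to the band's lower limit.
    Bands with undefined metrics are dropped pairwise (count logged in the
    ``n`` column).  Returns one row per trait_set × metric with the fitted
    parameters and the selected model.
    """
    rows = []
    for trait_set, sub in metric_frames.groupby("trait_set", sort=False):
        x = np.array([elevations[b] for b in sub["band"]])
        for col in value_columns:
            y = sub[col].to_numpy(dtype=float)
            finite = np.isfinite(y)
            if finite.sum() < 3 or np.ptp(y[finite]) == 0:
                continue
            fit = select_and_report(x, y)
            rows.append(
                {
                    "trait_set": trait_set,
                    "metric": col,
                    "selected_model": fit.selected_model,
                    "slope1": fit.slope1,
                    "slope2": fit.slope2,
                    "psi": fit.psi,
                    "t_slope1": fit.t_slope1,
                    "t_slope2": fit.t_slope2,
                    "r2": fit.r2,
                    "davies_p": fit.davies_p,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
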