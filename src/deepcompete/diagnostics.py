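"""Diagnostics for non-linearity and error phenomena in growth-rate tables.

These quantify, from fitted growth tables alone, the distortions the forward
simulator generates mechanistically: curvature between condition pairs
(co-transformation and lag effects inflate slow growers), standard-error
inflation for slow growers at late harvests, the closed-form lag bias and
its inversion, and concordance of shared variants across library
compositions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pairwise_correlations",
    "NonlinearityResult",
    "nonlinearity_index",
    "ErrorProfile",
    "se_vs_rate_profile",
    "predicted_lag_bias",
    "invert_lag_bias",
    "cross_library_concordance",
]


def pairwise_correlations(tables: dict | pd.DataFrame, min_shared: int = 2) -> pd.DataFrame:
    """Pearson correlation matrix between rate vectors.

    ``tables`` is either a wide DataFrame (variants x samples) or a dict of
    named Series; correlations use pairwise-complete finite entries and are
    NaN (flagged missing) when fewer than ``min_shared`` are available.
    """
    if isinstance(tables, dict):
        tables = pd.DataFrame(tables)
    return tables.corr(method="pearson", min_periods=min_shared)


@dataclass
class NonlinearityResult:
    """Standardised quadratic curvature between two rate vectors.

    ``index`` is the coefficient b2 of y = b0 + b1 z + b2 z^2 with z the
    z-scored x; positive means slow growers sit above the linear trend in y
    (the co-transformation / lag signature).
    """

    index: float
    coefficients: np.ndarray  # (b0, b1, b2)
    ci_low: float
    ci_high: float
    residual_sd: float
    n: int


def nonlinearity_index(
    x, y, n_boot: int = 1000, seed: int = 0, min_shared: int = 10
) -> NonlinearityResult:
    """Quadratic-in-z least-squares fit of y on standardised x.

    Bootstrap (``n_boot`` seeded resamples) gives a 95% CI on the curvature
    coefficient.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_shared:
        raise ValueError(f"need at least {min_shared} shared variants, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate x: zero variance")

    def _fit(xv, yv):
        z = (xv - xv.mean()) / xv.std(ddof=1)
        design = np.column_stack([np.ones_like(z), z, z**2])
        beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
        return beta, design

    beta, design = _fit(x, y)
    resid = y - design @ beta
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        xb = x[idx]
        if xb.std(ddof=1) == 0:
            boot[b] = np.nan
            continue
        boot[b] = _fit(xb, y[idx])[0][2]
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return NonlinearityResult(
        index=float(beta[2]),
        coefficients=beta,
        ci_low=float(lo),
        ci_high=float(hi),
        residual_sd=float(resid.std(ddof=1)),
        n=len(x),
    )


@dataclass
class ErrorProfile:
    """Decile-binned mean standard error versus mean growth rate."""

    bin_edges: np.ndarray
    mean_rate: np.ndarray
    mean_se: np.ndarray
    n_per_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "mean_rate": self.mean_rate,
                "mean_se": self.mean_se,
                "n": self.n_per_bin,
            }
        )


def se_vs_rate_profile(growth_table: pd.DataFrame, n_bins: int = 10) -> ErrorProfile:
    """Bin variants into rate deciles and average their replicate SEs.

    Requires a growth table with ``rate`` and ``se`` columns and SEs defined
    for at least one variant (n_replicates >= 2).
    """
    sub = growth_table.dropna(subset=["rate", "se"])
    if sub.empty:
        raise ValueError("no defined standard errors (need >= 2 replicates)")
    rates = sub["rate"].to_numpy()
    edges = np.unique(np.percentile(rates, np.linspace(0, 100, n_bins + 1)))
    which = np.clip(np.searchsorted(edges, rates, side="right") - 1, 0, len(edges) - 2)
    k = len(edges) - 1
    mean_rate = np.array([rates[which == i].mean() if np.any(which == i) else np.nan for i in range(k)])
    ses = sub["se"].to_numpy()
    mean_se = np.array([ses[which == i].mean() if np.any(which == i) else np.nan for i in range(k)])
    n = np.array([int(np.sum(which == i)) for i in range(k)])
    return ErrorProfile(edges, mean_rate, mean_se, n)


def predicted_lag_bias(g_true, r_lag: float, t_lag: float, total_hours: float):
    """Closed-form growth-rate estimate under a lag phase.

    With the input sample taken before methotrexate exposure, the estimate
    averages the lag rate over the lag and the true rate over the rest:
    g_hat = (r_lag t_lag + g (T - t_lag)) / T.
    """
    if total_hours <= t_lag:
        raise ValueError("total_hours must exceed t_lag")
    g = np.asarray(g_true, float)
    out = (r_lag * t_lag + g * (total_hours - t_lag)) / total_hours
    return float(out) if np.ndim(g_true) == 0 else out


def invert_lag_bias(g_hat, r_lag: float, t_lag: float, total_hours: float):
    """Invert the lag-bias map: g = (g_hat T - r_lag t_lag) / (T - t_lag)."""
    if total_hours <= t_lag:
        raise ValueError("total_hours must exceed t_lag")
    g = np.asarray(g_hat, float)
    out = (g * total_hours - r_lag * t_lag) / (total_hours - t_lag)
    return float(out) if np.ndim(g_hat) == 0 else out


def cross_library_concordance(
    tables: dict, component_of=None, min_shared: int = 10
) -> pd.DataFrame:
    """Concordance of shared variants between growth tables from different
    library compositions.

    ``tables`` maps library name -> rate Series indexed by variant id;
    ``component_of`` optionally maps a variant id to a shared component
    label (e.g. its bait partner) so concordance is reported per component.
    Returns one row per (library pair, component) with the number of shared
    variants, Pearson r and the mean paired rate difference (second minus
    first); pairs with insufficient overlap are flagged with NaN statistics.
    """
    names = list(tables)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = tables[a], tables[b]
            shared = sa.index.intersection(sb.index)
            if component_of is None:
                groups = {"all": shared}
            else:
                comp = pd.Series([component_of(v) for v in shared], index=shared)
                groups = {c: idx for c, idx in comp.groupby(comp).groups.items()}
            for comp_name, idx in groups.items():
                xa = sa.loc[idx].astype(float)
                xb = sb.loc[idx].astype(float)
                ok = np.isfinite(xa) & np.isfinite(xb)
                n = int(ok.sum())
                if n < min_shared:
                    rows.append((a, b, comp_name, n, np.nan, np.nan))
                    continue
                r = float(np.corrcoef(xa[ok], xb[ok])[0, 1]) if xa[ok].std() > 0 else np.nan
                rows.append((a, b, comp_name, n, r, float((xb[ok] - xa[ok]).mean())))
    return pd.DataFrame(
        rows, columns=["library_a", "library_b", "component", "n_shared", "pearson_r", "mean_delta"]
    )
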