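"""Model-adequacy diagnostics on normalized quantile residuals.

Under a correctly specified model the residuals r_i = Phi^-1(F(y_i; theta(x_i)))
are standard normal; three checks probe this: (1) residual-vs-covariate
scatter with a LOESS trend (systematic age/height patterns), (2) a normal
Q-Q plot (tail adequacy), (3) summary moments / histogram (overall shape).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import bcpe

log = logging.getLogger(__name__)

__all__ = [
    "ResidualDiagnostics",
    "quantile_residuals",
    "loess_smooth",
    "qq_normal",
    "compute_diagnostics",
]

_CLAMP = 1e-10


@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    ks_distance: float
    loess_curve: np.ndarray  # (grid, 2): covariate grid, smoothed residual
    qq_points: np.ndarray    # (n, 2): theoretical, sample quantiles
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": int(self.residuals.size),
            "mean": self.mean,
            "sd": self.sd,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
            "ks_distance": self.ks_distance,
            "loess_curve": self.loess_curve.tolist(),
            "qq_points": self.qq_points.tolist(),
            "hist_edges": self.hist_edges.tolist(),
            "hist_counts": self.hist_counts.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def quantile_residuals(results, y=None, x=None) -> np.ndarray:
    """Normalized quantile residuals of (y, x) under a fitted model.

    Defaults to the training data. CDF values of exactly 0 or 1 are clamped
    into (0, 1) with a warning so the probit stays finite.
    """
    if y is None or x is None:
        y = results.model.y
        x = results.model.x
    y = np.asarray(y, dtype=float)
    mu, sigma, nu = results._param_arrays(np.asarray(x, dtype=float))
    F = bcpe.cdf_arrays(y, mu, sigma, nu, results.tau_hat)
    n_clamped = int(np.sum((F <= 0) | (F >= 1)))
    if n_clamped:
        log.warning("clamped %d boundary CDF values in quantile residuals", n_clamped)
    F = np.clip(F, _CLAMP, 1.0 - _CLAMP)
    return stats.norm.ppf(F)


def loess_smooth(x, r, span: float = 0.5, n_grid: int = 100) -> np.ndarray:
    """Local linear regression with tricube weights over the span-nearest
    neighbors, evaluated on an n_grid-point grid over the data range.

    One pass (no robustifying reweighting). Returns an (n_grid, 2) array.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 points for LOESS")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    k = max(int(np.ceil(span * x.size)), 2)
    if k < 5:
        raise ValueError("span too small: fewer than 5 points in each window")
    order = np.argsort(x)
    xs, rs = x[order], r[order]
    grid = np.linspace(xs[0], xs[-1], n_grid)
    out = np.empty(n_grid)
    for j, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            out[j] = rs[idx].mean()
            continue
        w = (1.0 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        xw = xs[idx] - g
        W = np.sum(w)
        Sx = np.sum(w * xw)
        Sxx = np.sum(w * xw * xw)
        Sy = np.sum(w * rs[idx])
        Sxy = np.sum(w * xw * rs[idx])
        det = W * Sxx - Sx * Sx
        if det <= 1e-300:
            out[j] = Sy / W
        else:
            out[j] = (Sxx * Sy - Sx * Sxy) / det  # intercept = value at g
    return np.column_stack([grid, out])


def qq_normal(residuals) -> np.ndarray:
    """Normal Q-Q points: sorted residuals against Phi^-1((i - 0.5)/n)."""
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    if n < 20:
        raise ValueError("need at least 20 residuals")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo, r])


def _fd_edges(r: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis histogram bin edges."""
    q1, q3 = np.quantile(r, [0.25, 0.75])
    width = 2.0 * (q3 - q1) / r.size ** (1.0 / 3.0)
    if width <= 0:
        return np.linspace(r.min() - 0.5, r.max() + 0.5, 11)
    nbins = max(int(np.ceil((r.max() - r.min()) / width)), 1)
    return np.linspace(r.min(), r.max(), nbins + 1)


def compute_diagnostics(results, span: float = 0.5) -> ResidualDiagnostics:
    """All three residual checks for a fitted model (pure function of the
    model and its data; repeated calls are identical)."""
    r = quantile_residuals(results)
    x = np.asarray(results.model.x, dtype=float)
    edges = _fd_edges(r)
    counts, _ = np.histogram(r, bins=edges)
    ks = stats.kstest(r, "norm").statistic
    return ResidualDiagnostics(
        residuals=r,
        mean=float(np.mean(r)),
        sd=float(np.std(r, ddof=1)),
        skewness=float(stats.skew(r)),
        excess_kurtosis=float(stats.kurtosis(r)),
        ks_distance=float(ks),
        loess_curve=loess_smooth(x, r, span=span),
        qq_points=qq_normal(r),
        hist_edges=edges,
        hist_counts=counts,
    )


def plot_diagnostics(diag: ResidualDiagnostics, x=None, path=None):  # pragma: no cover
    """Optional three-panel figure (scatter+LOESS, Q-Q, histogram)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    if x is not None:
        axes[0].plot(x, diag.residuals, ".", ms=2, alpha=0.4)
    axes[0].plot(diag.loess_curve[:, 0], diag.loess_curve[:, 1], "r-", lw=2)
    axes[0].axhline(0, color="k", lw=0.8)
    axes[0].set(xlabel="covariate", ylabel="quantile residual")
    axes[1].plot(diag.qq_points[:, 0], diag.qq_points[:, 1], ".", ms=2)
    lim = [diag.qq_points[:, 0].min(), diag.qq_points[:, 0].max()]
    axes[1].plot(lim, lim, "r-", lw=1)
    axes[1].set(xlabel="theoretical quantile", ylabel="sample quantile")
    axes[2].stairs(diag.hist_counts, diag.hist_edges, fill=True)
    axes[2].set(xlabel="quantile residual", ylabel="count")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
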