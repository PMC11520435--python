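"""Posterior summarization and MCMC convergence diagnostics.

Each fitted quantile level is summarized as a table of posterior means and
95% equal-tailed credible intervals, with a coefficient flagged significant
when its interval excludes zero.  Convergence is assessed the way applied
MCMC work usually does: trace plots, marginal posterior density plots and
autocorrelation plots, exported here both as plain CSV payloads (so any
external tool can redraw them) and as rendered PNG images.  A numeric
convergence heuristic (autocorrelation decay plus a split-chain mean
comparison) is reported for convenience but never gates the pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .gibbs import PosteriorChain


@dataclass(frozen=True)
class CoefficientSummary:
    """Posterior mean, equal-tailed credible interval and significance flag."""

    label: str
    posterior_mean: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass(frozen=True)
class QuantileFitSummary:
    """One CoefficientSummary per design column, for a single tau."""

    tau: float
    rows: list[CoefficientSummary]

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coefficient": [r.label for r in self.rows],
                "posterior_mean": [r.posterior_mean for r in self.rows],
                "ci_low": [r.ci_low for r in self.rows],
                "ci_high": [r.ci_high for r in self.rows],
                "significant": [r.significant for r in self.rows],
            }
        )


def summarize_chain(chain: PosteriorChain, level: float = 0.95) -> QuantileFitSummary:
    """Posterior mean and equal-tailed ``level`` credible interval per coefficient.

    The interval endpoints are the (1-level)/2 and 1-(1-level)/2 empirical
    quantiles of the retained draws; a coefficient is flagged significant
    when zero lies outside the interval.  Degenerate (constant) chains are
    rejected because the interval would collapse to a point.
    """
    if chain.n_draws == 0:
        raise ValueError("cannot summarize an empty chain")
    if not 0.0 < level < 1.0:
        raise ValueError("credible level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lows = np.quantile(chain.draws, alpha, axis=0)
    highs = np.quantile(chain.draws, 1.0 - alpha, axis=0)
    means = chain.draws.mean(axis=0)
    rows = []
    for j, label in enumerate(chain.column_labels):
        if not lows[j] < highs[j]:
            raise ValueError(
                f"degenerate credible interval for '{label}': the chain is constant"
            )
        sig = (0.0 < lows[j]) or (0.0 > highs[j])
        rows.append(
            CoefficientSummary(
                label=label,
                posterior_mean=float(means[j]),
                ci_low=float(lows[j]),
                ci_high=float(highs[j]),
                significant=bool(sig),
            )
        )
    return QuantileFitSummary(tau=chain.tau, rows=rows)


def autocorrelation(series, max_lag: int) -> np.ndarray:
    """Empirical autocorrelation at lags 0..max_lag with overall-mean centering.

    r_k = sum_{t} (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2, so the
    lag-0 value is exactly 1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.shape[0]
    if n <= max_lag:
        raise ValueError(f"series length {n} must exceed max_lag {max_lag}")
    centered = x - x.mean()
    denom = float(np.dot(centered, centered))
    if denom == 0.0:
        raise ValueError("autocorrelation undefined for a zero-variance series")
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = np.dot(centered[: n - k], centered[k:]) / denom
    return acf


def density_curve(series, n_points: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate with the rule-of-thumb bandwidth."""
    from scipy import stats

    x = np.asarray(series, dtype=float)
    if np.std(x) == 0.0:
        raise ValueError("density undefined for a zero-variance series")
    kde = stats.gaussian_kde(x)  # Scott's rule bandwidth
    grid = np.linspace(x.min() - 3 * kde.factor * x.std(), x.max() + 3 * kde.factor * x.std(), n_points)
    return grid, kde(grid)


def convergence_heuristic(chain: PosteriorChain, lag: int = 1) -> dict[str, float]:
    """Informal numeric check: max |acf(lag)| and max split-chain mean gap.

    The gap is |mean(first half) - mean(second half)| in units of the
    coefficient's posterior standard deviation.  Purely advisory.
    """
    m = chain.n_draws
    half = m // 2
    max_acf = 0.0
    max_gap = 0.0
    for j in range(chain.draws.shape[1]):
        col = chain.draws[:, j]
        sd = col.std()
        if sd == 0:
            continue
        max_acf = max(max_acf, abs(float(autocorrelation(col, lag)[lag])))
        max_gap = max(max_gap, abs(float(col[:half].mean() - col[half:].mean())) / sd)
    return {"max_abs_acf": max_acf, "max_split_mean_gap_sd": max_gap}


def export_diagnostics(chain: PosteriorChain, out_dir, max_lag: int = 40) -> list[str]:
    """Write trace/density/acf CSV payloads and PNG plots per coefficient.

    Filenames encode the quantile level and coefficient label, e.g.
    ``trace_tau0.85_AGE.csv``.  Returns the list of paths written; the CSV
    payloads are deterministic given the chain.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    tag = f"tau{chain.tau:g}"
    written: list[str] = []

    def _safe(label: str) -> str:
        return "".join(c if c.isalnum() or c in "-_." else "_" for c in label)

    for j, label in enumerate(chain.column_labels):
        col = chain.draws[:, j]
        slug = f"{tag}_{_safe(label)}"

        trace_path = os.path.join(out_dir, f"trace_{slug}.csv")
        pd.DataFrame({"draw": np.arange(1, col.size + 1), "value": col}).to_csv(
            trace_path, index=False
        )
        written.append(trace_path)

        grid, dens = density_curve(col)
        dens_path = os.path.join(out_dir, f"density_{slug}.csv")
        pd.DataFrame({"value": grid, "density": dens}).to_csv(dens_path, index=False)
        written.append(dens_path)

        acf = autocorrelation(col, min(max_lag, col.size - 1))
        acf_path = os.path.join(out_dir, f"acf_{slug}.csv")
        pd.DataFrame({"lag": np.arange(acf.size), "acf": acf}).to_csv(acf_path, index=False)
        written.append(acf_path)

        fig, axes = plt.subplots(1, 3, figsize=(11, 3))
        axes[0].plot(col, lw=0.5)
        axes[0].set_title(f"trace {label}")
        axes[1].plot(grid, dens)
        axes[1].set_title(f"density {label}")
        axes[2].bar(np.arange(acf.size), acf, width=0.8)
        axes[2].set_title(f"acf {label}")
        fig.suptitle(f"tau = {chain.tau:g}")
        fig.tight_layout()
        png_path = os.path.join(out_dir, f"diagnostics_{slug}.png")
        try:
            fig.savefig(png_path, dpi=100)
        except OSError as exc:
            raise OSError(f"failed to write diagnostic plot {png_path}: {exc}") from exc
        finally:
            plt.close(fig)
        written.append(png_path)

    return written
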