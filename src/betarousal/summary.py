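"""Posterior summaries: HDIs, credibility decisions, tail probabilities,
and Bayesian R-squared.

The 95% highest-density interval (HDI / HPD95) is the shortest contiguous
interval containing 95% of the posterior draws; an effect is "credible"
when its HDI excludes zero.  Bayesian R² is one minus the ratio of residual
variance to data variance, computed per posterior draw and then averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SummaryResult:
    name: str
    posterior_mean: float
    hdi_low: float
    hdi_high: float
    credible: bool
    tail_prob: float
    n_draws: int

    def as_row(self) -> dict:
        return {
            "name": self.name, "estimate": self.posterior_mean,
            "hdi_low": self.hdi_low, "hdi_high": self.hdi_high,
            "credible": self.credible, "tail_prob": self.tail_prob,
            "n_draws": self.n_draws,
        }


@dataclass
class R2Result:
    model: str
    r2: float
    reduced_model: str | None = None
    r2_change: float | None = None


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws.

    Exact for the empirical distribution (sorted-window search).  Multimodal
    samples still yield a single contiguous interval, with a warning.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HDI, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))
    _warn_if_multimodal(x)
    return float(x[k]), float(x[k + m - 1])


def _warn_if_multimodal(sorted_draws: np.ndarray) -> None:
    """Cheap histogram-valley heuristic; only used to warn."""
    x = sorted_draws
    span = x[-1] - x[0]
    if span <= 0 or not np.isfinite(span) \
            or span < 1e-12 * max(1.0, abs(x[0])):
        return
    try:
        counts, _ = np.histogram(x, bins=30)
    except ValueError:
        return
    s = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    peak = s.max()
    # flag a deep interior valley separating two substantial masses
    high = s > 0.5 * peak
    lo_idx = np.flatnonzero(high)
    if lo_idx.size < 2:
        return
    interior = s[lo_idx[0]: lo_idx[-1] + 1]
    if interior.min() < 0.15 * peak:
        warnings.warn("posterior draws look multimodal; HDI reported as a "
                      "single contiguous interval", stacklevel=3)


def tail_probability(draws, direction: str = "below") -> float:
    """Fraction of draws below (or above) zero."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 draws")
    if direction == "below":
        return float(np.mean(x < 0.0))
    if direction == "above":
        return float(np.mean(x > 0.0))
    raise ValueError("direction must be 'below' or 'above'")


def credible_flag(hdi_low: float, hdi_high: float) -> bool:
    """True iff zero lies outside [hdi_low, hdi_high]."""
    return hdi_low > 0.0 or hdi_high < 0.0


def summarize(draws, name: str, mass: float = 0.95) -> SummaryResult:
    x = np.asarray(draws, dtype=float).ravel()
    lo, hi = hdi(x, mass)
    p_below = float(np.mean(x < 0.0))
    return SummaryResult(
        name=name,
        posterior_mean=float(np.mean(x)),
        hdi_low=lo, hdi_high=hi,
        credible=credible_flag(lo, hi),
        tail_prob=float(min(p_below, 1.0 - p_below)),
        n_draws=x.size,
    )


def summary_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def bayesian_r2(predict, y, model: str = "model", n_eval: int = 1000,
                at_posterior_mean: bool = False) -> R2Result:
    """Bayesian R² = 1 - var(residuals) / var(data).

    Parameters
    ----------
    predict : callable(n_draws) -> ndarray (n_draws, n_obs)
        Returns pointwise predictions for a thinned subset of posterior
        draws (the model's ``FitResult.predictions``).
    y : observed outcome vector.
    at_posterior_mean : if True, compute the variance ratio at the
        posterior-mean prediction instead of averaging per-draw values.
    """
    y = np.asarray(y, dtype=float)
    vy = float(np.var(y))
    if vy <= 0.0:
        raise ValueError("zero data variance")
    preds = np.asarray(predict(n_eval))
    if at_posterior_mean:
        resid = y - preds.mean(axis=0)
        return R2Result(model=model, r2=float(1.0 - np.var(resid) / vy))
    resid_var = np.var(y[None, :] - preds, axis=1)
    r2_draws = 1.0 - resid_var / vy
    return R2Result(model=model, r2=float(np.mean(r2_draws)))


def r2_change(full: R2Result, reduced: R2Result) -> R2Result:
    return R2Result(model=full.model, r2=full.r2,
                    reduced_model=reduced.model,
                    r2_change=full.r2 - reduced.r2)
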