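"""Hierarchical Bayesian model families.

Three families, all Gaussian with vague priors and exact block-Gibbs
updates (see :mod:`betarousal.mcmc`):

* **Within-subject factorial ANOVA** — one mean per design cell, a normal
  subject effect (random intercept), homogeneous residual SD.  Cell means
  get Normal(0, (100·sd(y))²) priors; SDs get Uniform(0, 10·sd(y)) priors.
  Identifiability of cell means against the subject-effect average is
  handled by a translation-group sweep move during sampling and by
  reporting the identified quantities mu_cell + mean(subject effects).
* **Between-subject regression** — subject-level reactivity (difference of
  mean z-responses between the 80% and 40% active cells) on centered trait
  predictors.
* **Trial-level ANCOVA** — within-subject z-scored bet on win-probability
  cell effects, a subject random intercept, and a trial-level z-scored
  peripheral covariate.

Every fit returns a :class:`FitResult` with the posterior draws, the
convergence gate (max split-R-hat < 1.1 by default), and a thinned
pointwise-prediction hook for Bayesian R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mcmc
from .config import McmcConfig
from .mcmc import GibbsBlock, ModelSpec, PosteriorDraws
from .summary import SummaryResult, summarize

_PRIOR_MEAN_SCALE = 100.0   # prior SD on means/coefs, in units of sd(y)
_PRIOR_SD_SCALE = 10.0      # upper bound of the uniform SD prior, ditto


@dataclass
class FitResult:
    model: str
    draws: PosteriorDraws
    cells: list
    converged: bool
    rhat_max: float
    ess_min: float
    outcome: np.ndarray
    _predict: callable = None
    subjects: list | None = None
    flags: list | None = None

    def cell_draws(self, cell: str) -> np.ndarray:
        """Pooled draws of one identified cell mean."""
        k = self.cells.index(cell)
        mu = self.draws.flat("mu")[:, k]
        if "s" in self.draws.draws:
            mu = mu + self.draws.flat("s").mean(axis=1)
        return mu

    def predictions(self, n_eval: int = 1000) -> np.ndarray:
        """Pointwise predictions for a thinned subset of draws."""
        total = self.draws.total_draws
        idx = np.linspace(0, total - 1, min(n_eval, total)).astype(int)
        return self._predict(idx)


def _gate(draws: PosteriorDraws, rhat_gate: float) -> tuple[bool, float, float]:
    rh = mcmc.gelman_rubin(draws)
    es = mcmc.effective_sample_size(draws)
    rmax = max(rh.values())
    emin = min(es.values())
    return rmax < rhat_gate, rmax, emin


def _sd_prior_init(upper):
    return lambda rng: np.array([rng.uniform(0.05 * upper, upper)])


# ---------------------------------------------------------------------------
# within-subject cell-means ANOVA
# ---------------------------------------------------------------------------

def fit_anova(data: pd.DataFrame, outcome: str, cell_col: str = "cell",
              subject_col: str = "subject_id",
              settings: McmcConfig | None = None, seed: int = 0,
              priors: dict | None = None) -> FitResult:
    """Hierarchical cell-means ANOVA with a subject random intercept.

    Rows with a missing outcome are dropped (missingness propagates by row
    deletion in this model only).  Requires at least two subjects per cell.
    """
    settings = settings or McmcConfig()
    priors = priors or {}
    df = data.dropna(subset=[outcome])
    counts = df.groupby(cell_col)[subject_col].nunique()
    cells = sorted(df[cell_col].unique())
    if (counts < 2).any() or len(cells) == 0:
        raise ValueError("need >= 2 subjects with data in every cell")

    y = df[outcome].to_numpy(dtype=float)
    c = pd.Categorical(df[cell_col], categories=cells).codes.astype(int)
    subjects = sorted(df[subject_col].unique())
    j = pd.Categorical(df[subject_col], categories=subjects).codes.astype(int)
    n, C, J = len(y), len(cells), len(subjects)
    sd_y = max(float(np.std(y)), 1e-12)
    tau = priors.get("mean_sd", _PRIOR_MEAN_SCALE * sd_y)
    upper = priors.get("sd_upper", _PRIOR_SD_SCALE * sd_y)
    n_c = np.bincount(c, minlength=C).astype(float)
    n_j = np.bincount(j, minlength=J).astype(float)

    def draw_mu(state, rng):
        r = y - state["s"][j]
        se2 = state["sigma_e"][0] ** 2
        prec = n_c / se2 + 1.0 / tau ** 2
        mean = (np.bincount(c, weights=r, minlength=C) / se2) / prec
        return mean + rng.standard_normal(C) / np.sqrt(prec)

    def draw_s(state, rng):
        r = y - state["mu"][c]
        se2 = state["sigma_e"][0] ** 2
        prec = n_j / se2 + 1.0 / state["sigma_s"][0] ** 2
        mean = (np.bincount(j, weights=r, minlength=J) / se2) / prec
        return mean + rng.standard_normal(J) / np.sqrt(prec)

    def sweep(state, rng):
        # translation-group move between cell means and subject effects
        ss2 = state["sigma_s"][0] ** 2
        prec = J / ss2 + C / tau ** 2
        mean = (state["s"].sum() / ss2 - state["mu"].sum() / tau ** 2) / prec
        delta = mean + rng.standard_normal() / np.sqrt(prec)
        state["s"] = state["s"] - delta
        return state["mu"] + delta

    def draw_sigma_e(state, rng):
        resid = y - state["mu"][c] - state["s"][j]
        v = mcmc.truncated_invgamma_variance(
            (n - 1) / 2.0, float(resid @ resid) / 2.0, upper ** 2, rng)
        return np.array([np.sqrt(v)])

    def draw_sigma_s(state, rng):
        s = state["s"]
        v = mcmc.truncated_invgamma_variance(
            (J - 1) / 2.0, float(s @ s) / 2.0, upper ** 2, rng)
        return np.array([max(np.sqrt(v), 1e-8)])

    def draw_sigma_s_asis(state, rng):
        # interweaving (non-centered) update: treat s_tilde = s/sigma_s as
        # N(0,1) ancillaries and sigma_s as a regression coefficient on
        # them; breaks the funnel when the subject SD is near zero
        s_tilde = state["s"] / state["sigma_s"][0]
        z = s_tilde[j]
        denom = float(z @ z)
        if denom <= 0.0:
            return state["sigma_s"]
        r = y - state["mu"][c]
        se = state["sigma_e"][0]
        mean = float(z @ r) / denom
        sd = se / np.sqrt(denom)
        new = max(mcmc.truncated_normal(mean, sd, 0.0, upper, rng), 1e-8)
        state["s"] = s_tilde * new
        return np.array([new])

    mu_init = lambda rng: rng.normal(0.0, sd_y, C)  # noqa: E731
    spec = ModelSpec(name=f"anova[{outcome}]", blocks=[
        GibbsBlock("mu", mu_init, draw_mu),
        GibbsBlock("s", lambda rng: rng.normal(0.0, 0.5 * sd_y, J), draw_s),
        # the sweep rewrites "mu" (and "s" in place): translation move
        GibbsBlock("mu", mu_init, sweep),
        GibbsBlock("sigma_e", _sd_prior_init(upper), draw_sigma_e),
        GibbsBlock("sigma_s", _sd_prior_init(upper), draw_sigma_s),
        GibbsBlock("sigma_s", _sd_prior_init(upper), draw_sigma_s_asis),
    ], tracked=["mu", "s", "sigma_e", "sigma_s"])

    draws = mcmc.sample(spec, settings.n_chains, settings.n_iter,
                        settings.burn_in, seed)
    converged, rmax, emin = _gate(draws, settings.rhat_gate)

    def predict(idx):
        mu = draws.flat("mu")[idx]
        s = draws.flat("s")[idx]
        return mu[:, c] + s[:, j]

    return FitResult(model=spec.name, draws=draws, cells=cells,
                     converged=converged, rhat_max=rmax, ess_min=emin,
                     outcome=y, _predict=predict, subjects=subjects)


def contrast(fit: FitResult, weights: dict, name: str) -> SummaryResult:
    """Posterior of a weighted sum of identified cell means."""
    unknown = set(weights) - set(fit.cells)
    if unknown:
        raise KeyError(f"contrast references unknown cells: {sorted(unknown)}")
    return summarize(_contrast_draws(fit, weights), name)


INTERACTION_WEIGHTS = {"A80": 1.0, "A40": -1.0, "N80": -1.0, "N40": 1.0}


def subgroup_difference(fit_a: FitResult, fit_b: FitResult, weights: dict,
                        name: str) -> SummaryResult:
    """Difference of the same contrast between two independently fitted
    subgroups (posteriors paired draw-by-draw)."""
    da = _contrast_draws(fit_a, weights)
    db = _contrast_draws(fit_b, weights)
    m = min(da.size, db.size)
    return summarize(da[:m] - db[:m], name)


def _contrast_draws(fit: FitResult, weights: dict) -> np.ndarray:
    mu = fit.draws.flat("mu")
    total = np.zeros(mu.shape[0])
    for cell, w in weights.items():
        total = total + w * mu[:, fit.cells.index(cell)]
    wsum = sum(weights.values())
    if wsum != 0.0 and "s" in fit.draws.draws:
        total = total + wsum * fit.draws.flat("s").mean(axis=1)
    return total


# ---------------------------------------------------------------------------
# between-subject trait regression
# ---------------------------------------------------------------------------

def reactivity_outcome(z_responses: pd.DataFrame, z_col: str,
                       high: str = "A80", low: str = "A40") -> pd.Series:
    """Per-subject reactivity: mean z-response in A80 minus in A40."""
    means = z_responses.pivot_table(index="subject_id", columns="cell",
                                    values=z_col, aggfunc="mean")
    return (means[high] - means[low]).dropna()


def fit_regression(outcome: pd.Series, predictors: pd.DataFrame,
                   settings: McmcConfig | None = None, seed: int = 0,
                   priors: dict | None = None) -> FitResult:
    """Bayesian linear regression of subject reactivity on centered traits.

    ``outcome`` and ``predictors`` are aligned on subject id; subjects with
    any missing value are dropped.  Collinear or constant predictors flag
    the fit rather than failing silently.
    """
    settings = settings or McmcConfig()
    priors = priors or {}
    df = predictors.join(outcome.rename("_y"), how="inner").dropna()
    if len(df) < 10:
        raise ValueError("need >= 10 subjects with complete data")
    names = list(predictors.columns)
    y = df["_y"].to_numpy(dtype=float)
    X = df[names].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    flags = []
    sds = X.std(axis=0)
    if np.any(sds == 0.0):
        raise ValueError("constant predictor (zero variance)")
    if len(names) > 1:
        cond = np.linalg.cond(X / sds)
        if cond > 1e6:
            flags.append(f"collinear design (condition number {cond:.2g})")
    Xd = np.column_stack([np.ones(len(y)), X])
    K = Xd.shape[1]
    sd_y = max(float(np.std(y)), 1e-12)
    tau = priors.get("mean_sd", _PRIOR_MEAN_SCALE * sd_y)
    upper = priors.get("sd_upper", _PRIOR_SD_SCALE * sd_y)
    XtX = Xd.T @ Xd
    Xty = Xd.T @ y
    n = len(y)

    def draw_beta(state, rng):
        se2 = state["sigma"][0] ** 2
        prec = XtX / se2 + np.eye(K) / tau ** 2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xty / se2)
        z = rng.standard_normal(K)
        return mean + np.linalg.solve(chol.T, z)

    def draw_sigma(state, rng):
        resid = y - Xd @ state["beta"]
        v = mcmc.truncated_invgamma_variance(
            (n - 1) / 2.0, float(resid @ resid) / 2.0, upper ** 2, rng)
        return np.array([np.sqrt(v)])

    spec = ModelSpec(name=f"regression[{'+'.join(names)}]", blocks=[
        GibbsBlock("beta", lambda rng: rng.normal(0, sd_y, K), draw_beta),
        GibbsBlock("sigma", _sd_prior_init(upper), draw_sigma),
    ])
    draws = mcmc.sample(spec, settings.n_chains, settings.n_iter,
                        settings.burn_in, seed)
    converged, rmax, emin = _gate(draws, settings.rhat_gate)

    def predict(idx):
        return draws.flat("beta")[idx] @ Xd.T

    fit = FitResult(model=spec.name, draws=draws,
                    cells=["intercept"] + names, converged=converged,
                    rhat_max=rmax, ess_min=emin, outcome=y,
                    _predict=predict, flags=flags)
    return fit


def coefficient_summary(fit: FitResult, name: str) -> SummaryResult:
    k = fit.cells.index(name)
    return summarize(fit.draws.flat("beta")[:, k], name)


# ---------------------------------------------------------------------------
# trial-level ANCOVA
# ---------------------------------------------------------------------------

def fit_ancova(data: pd.DataFrame, covariate: str | None,
               outcome: str = "chosen_bet", settings: McmcConfig | None = None,
               seed: int = 0, priors: dict | None = None) -> FitResult:
    """Bet-size ANCOVA on active-choice trials.

    The outcome is z-scored within subject; fixed win-probability effects,
    a subject random intercept, and (optionally) a trial-level covariate —
    the z-scored peripheral response.  ``covariate=None`` fits the reduced
    model (for R² change).
    """
    settings = settings or McmcConfig()
    priors = priors or {}
    df = data[data["condition"] == "active"].copy()
    needed = [outcome] + ([covariate] if covariate else [])
    if covariate and df[covariate].isna().mean() > 0.5:
        raise ValueError("covariate missing on more than 50% of trials")
    df = df.dropna(subset=needed)
    subjects = sorted(df["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    grp = df.groupby("subject_id")[outcome]
    df["_zy"] = (df[outcome] - grp.transform("mean")) / grp.transform(
        lambda s: s.std(ddof=1))
    df["_zy"] = df["_zy"].replace([np.inf, -np.inf], np.nan)
    df = df.dropna(subset=["_zy"])
    subjects = sorted(df["subject_id"].unique())

    y = df["_zy"].to_numpy(dtype=float)
    levels = sorted(df["win_prob"].unique())
    p = pd.Categorical(df["win_prob"], categories=levels).codes.astype(int)
    j = pd.Categorical(df["subject_id"],
                       categories=subjects).codes.astype(int)
    x = df[covariate].to_numpy(dtype=float) if covariate else None
    n, P, J = len(y), len(levels), len(subjects)
    sd_y = max(float(np.std(y)), 1e-12)
    tau = priors.get("mean_sd", _PRIOR_MEAN_SCALE * sd_y)
    upper = priors.get("sd_upper", _PRIOR_SD_SCALE * sd_y)
    n_p = np.bincount(p, minlength=P).astype(float)
    n_j = np.bincount(j, minlength=J).astype(float)
    sxx = float(x @ x) if covariate else 0.0

    def resid(state, skip):
        r = y.copy()
        if skip != "mu":
            r -= state["mu"][p]
        if skip != "u":
            r -= state["u"][j]
        if covariate and skip != "beta":
            r -= state["beta"][0] * x
        return r

    def draw_mu(state, rng):
        r = resid(state, "mu")
        se2 = state["sigma_e"][0] ** 2
        prec = n_p / se2 + 1.0 / tau ** 2
        mean = (np.bincount(p, weights=r, minlength=P) / se2) / prec
        return mean + rng.standard_normal(P) / np.sqrt(prec)

    def draw_u(state, rng):
        r = resid(state, "u")
        se2 = state["sigma_e"][0] ** 2
        prec = n_j / se2 + 1.0 / state["sigma_u"][0] ** 2
        mean = (np.bincount(j, weights=r, minlength=J) / se2) / prec
        return mean + rng.standard_normal(J) / np.sqrt(prec)

    def sweep(state, rng):
        su2 = state["sigma_u"][0] ** 2
        prec = J / su2 + P / tau ** 2
        mean = (state["u"].sum() / su2 - state["mu"].sum() / tau ** 2) / prec
        delta = mean + rng.standard_normal() / np.sqrt(prec)
        state["u"] = state["u"] - delta
        return state["mu"] + delta

    def draw_beta(state, rng):
        r = resid(state, "beta")
        se2 = state["sigma_e"][0] ** 2
        prec = sxx / se2 + 1.0 / tau ** 2
        mean = float(x @ r) / se2 / prec
        return np.array([mean + rng.standard_normal() / np.sqrt(prec)])

    def draw_sigma_e(state, rng):
        r = resid(state, "none")
        v = mcmc.truncated_invgamma_variance(
            (n - 1) / 2.0, float(r @ r) / 2.0, upper ** 2, rng)
        return np.array([np.sqrt(v)])

    def draw_sigma_u(state, rng):
        u = state["u"]
        v = mcmc.truncated_invgamma_variance(
            (J - 1) / 2.0, float(u @ u) / 2.0, upper ** 2, rng)
        return np.array([max(np.sqrt(v), 1e-8)])

    def draw_sigma_u_asis(state, rng):
        u_tilde = state["u"] / state["sigma_u"][0]
        z = u_tilde[j]
        denom = float(z @ z)
        if denom <= 0.0:
            return state["sigma_u"]
        r = y - state["mu"][p]
        if covariate:
            r = r - state["beta"][0] * x
        se = state["sigma_e"][0]
        mean = float(z @ r) / denom
        sd = se / np.sqrt(denom)
        new = max(mcmc.truncated_normal(mean, sd, 0.0, upper, rng), 1e-8)
        state["u"] = u_tilde * new
        return np.array([new])

    blocks = [
        GibbsBlock("mu", lambda rng: rng.normal(0, sd_y, P), draw_mu),
        GibbsBlock("u", lambda rng: rng.normal(0, 0.5 * sd_y, J), draw_u),
        GibbsBlock("mu", lambda rng: np.zeros(P), sweep),
    ]
    tracked = ["mu", "u", "sigma_e", "sigma_u"]
    if covariate:
        blocks.append(GibbsBlock(
            "beta", lambda rng: rng.normal(0, sd_y, 1), draw_beta))
        tracked.append("beta")
    blocks += [
        GibbsBlock("sigma_e", _sd_prior_init(upper), draw_sigma_e),
        GibbsBlock("sigma_u", _sd_prior_init(upper), draw_sigma_u),
        GibbsBlock("sigma_u", _sd_prior_init(upper), draw_sigma_u_asis),
    ]
    covname = covariate or "none"
    spec = ModelSpec(name=f"ancova[{outcome}~{covname}]", blocks=blocks,
                     tracked=tracked)
    draws = mcmc.sample(spec, settings.n_chains, settings.n_iter,
                        settings.burn_in, seed)
    converged, rmax, emin = _gate(draws, settings.rhat_gate)

    def predict(idx):
        mu = draws.flat("mu")[idx]
        u = draws.flat("u")[idx]
        pred = mu[:, p] + u[:, j]
        if covariate:
            pred = pred + draws.flat("beta")[idx] * x[None, :]
        return pred

    return FitResult(model=spec.name, draws=draws,
                     cells=[f"p{int(round(l * 100))}" for l in levels],
                     converged=converged, rhat_max=rmax, ess_min=emin,
                     outcome=y, _predict=predict, subjects=subjects)


def ancova_beta(fit: FitResult, name: str = "beta") -> SummaryResult:
    return summarize(fit.draws.flat("beta")[:, 0], name)
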