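"""Model-family behavior on directly simulated data with known truth."""

import numpy as np
import pandas as pd
import pytest

from betarousal import models
from betarousal.config import CELLS, McmcConfig


def _anova_data(truth, n_subj=40, per_cell=12, sigma=1.0, subj_sd=0.3,
                seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_subj):
        s = rng.normal(0, subj_sd)
        for ci, cell in enumerate(CELLS):
            for v in truth[ci] + s + rng.normal(0, sigma, per_cell):
                rows.append({"subject_id": f"S{j:03d}", "cell": cell,
                             "y": v})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def anova_fit():
    truth = np.array([-0.12, 0.0, 0.12, 0.05, 0.0, -0.05])
    df = _anova_data(truth, n_subj=60, per_cell=15, seed=42)
    mc = McmcConfig(n_chains=4, n_iter=1200, burn_in=500)
    return truth, models.fit_anova(df, "y", settings=mc, seed=1)


class TestAnova:
    def test_cell_means_recovered(self, anova_fit):
        """Posterior cell means within 0.1 of truth at n=60 x 15/cell."""
        truth, fit = anova_fit
        assert fit.converged
        est = np.array([fit.cell_draws(c).mean() for c in CELLS])
        # remove the common shift (the realized subject-effect average is
        # part of the identified cell means)
        assert np.abs((est - est.mean()) - (truth - truth.mean())).max() < 0.1

    def test_interaction_contrast_recovered(self, anova_fit):
        truth, fit = anova_fit
        res = models.contrast(fit, models.INTERACTION_WEIGHTS, "interaction")
        injected = (truth[2] - truth[0]) - (truth[5] - truth[3])
        assert res.hdi_low < injected < res.hdi_high
        assert res.credible and res.posterior_mean > 0

    def test_zero_weights_degenerate_at_zero(self, anova_fit):
        _, fit = anova_fit
        res = models.contrast(fit, {c: 0.0 for c in CELLS}, "null")
        assert res.posterior_mean == 0.0
        assert (res.hdi_low, res.hdi_high) == (0.0, 0.0)

    def test_unknown_cell_rejected(self, anova_fit):
        _, fit = anova_fit
        with pytest.raises(KeyError):
            models.contrast(fit, {"Z99": 1.0}, "bad")

    def test_sparse_cell_rejected(self):
        df = _anova_data(np.zeros(6), n_subj=5, per_cell=2, seed=0)
        df = df[~((df["cell"] == "A40")
                  & (df["subject_id"] != "S000"))]
        with pytest.raises(ValueError):
            models.fit_anova(df, "y", settings=McmcConfig(4, 100, 50))

    def test_borrowing_strength_shrinks_subject_effects(self, fast_mcmc):
        """Hierarchical subject-effect estimates are less dispersed than
        the raw per-subject means (shrinkage toward the group)."""
        rng = np.random.default_rng(7)
        rows = []
        for j in range(25):
            s = rng.normal(0, 0.2)
            n_j = rng.integers(3, 25)   # unbalanced
            for ci in rng.integers(0, 6, n_j):
                rows.append({"subject_id": f"S{j:02d}", "cell": CELLS[ci],
                             "y": s + rng.normal(0, 1.0)})
        df = pd.DataFrame(rows)
        fit = models.fit_anova(df, "y", settings=fast_mcmc, seed=3)
        post_s = fit.draws.flat("s").mean(axis=0)
        raw = df.groupby("subject_id")["y"].mean()
        raw = (raw - raw.mean()).to_numpy()
        assert np.std(post_s) < np.std(raw)


class TestRegression:
    @staticmethod
    def _trait_data(n=63, seed=0, noise=0.28):
        rng = np.random.default_rng(seed)
        bis = rng.normal(21, 3.6, n)
        bas = rng.normal(39.5, 5.3, n)
        y = 0.05 * (bis - bis.mean()) - 0.03 * (bas - bas.mean()) \
            + rng.normal(0, noise, n)
        idx = [f"S{i:03d}" for i in range(n)]
        return (pd.Series(y, index=idx, name="react"),
                pd.DataFrame({"bis": bis, "bas": bas}, index=idx))

    def test_signs_recovered_and_credible(self, fast_mcmc):
        outcome, preds = self._trait_data()
        fit = models.fit_regression(outcome, preds, settings=fast_mcmc,
                                    seed=2)
        b_bis = models.coefficient_summary(fit, "bis")
        b_bas = models.coefficient_summary(fit, "bas")
        assert b_bis.posterior_mean > 0 and b_bis.credible
        assert b_bas.posterior_mean < 0 and b_bas.credible
        assert abs(b_bis.posterior_mean - 0.05) < 0.03
        assert abs(b_bas.posterior_mean + 0.03) < 0.02

    def test_pure_noise_covers_zero_in_most_replicates(self, fast_mcmc):
        """Null simulation: with pure-noise reactivity each beta's 95% HDI
        covers zero in >= 80% of replicates (5% miss rate expected)."""
        covered = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(9000 + rep)
            outcome, preds = self._trait_data(seed=100 + rep)
            outcome[:] = rng.normal(0, 0.3, len(outcome))
            fit = models.fit_regression(outcome, preds, settings=fast_mcmc,
                                        seed=rep)
            covered += sum(
                not models.coefficient_summary(fit, t).credible
                for t in ("bis", "bas"))
        assert covered >= 0.8 * 2 * n_rep

    def test_duplicated_predictor_flagged(self, fast_mcmc):
        outcome, preds = self._trait_data()
        preds = preds.assign(bis_copy=preds["bis"])
        fit = models.fit_regression(outcome, preds, settings=fast_mcmc,
                                    seed=7)
        assert fit.flags and "collinear" in fit.flags[0]

    def test_constant_predictor_rejected(self, fast_mcmc):
        outcome, preds = self._trait_data()
        preds = preds.assign(const=1.0)
        with pytest.raises(ValueError, match="constant predictor"):
            models.fit_regression(outcome, preds, settings=fast_mcmc)

    def test_too_few_subjects_rejected(self, fast_mcmc):
        outcome, preds = self._trait_data(n=8)
        with pytest.raises(ValueError):
            models.fit_regression(outcome, preds, settings=fast_mcmc)


def _ancova_data(beta=0.2, n_subj=40, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    p_eff = {0.4: -0.6, 0.6: 0.0, 0.8: 0.6}
    for j in range(n_subj):
        u = rng.normal(0, 0.3)
        for p, eff in p_eff.items():
            for _ in range(15):
                x = rng.standard_normal()
                y = eff + u + beta * x + rng.normal(0, 0.6)
                rows.append({"subject_id": f"S{j:02d}", "condition": "active",
                             "win_prob": p, "bet": y, "x": x})
    return pd.DataFrame(rows)


class TestAncova:
    def test_covariate_weight_matches_ols_oracle(self, fast_mcmc):
        """The Gibbs ANCOVA posterior mean agrees with the closed-form
        within-subject-within-cell least-squares slope on the identical
        (z-scored) data, and recovers the injected coupling."""
        df = _ancova_data(beta=0.2, seed=1)
        fit = models.fit_ancova(df, "x", outcome="bet", settings=fast_mcmc,
                                seed=1)
        res = models.ancova_beta(fit)
        g = df.groupby("subject_id")["bet"]
        df["zy"] = (df["bet"] - g.transform("mean")) \
            / g.transform(lambda s: s.std(ddof=1))
        ry = df["zy"] - df.groupby(["subject_id", "win_prob"])["zy"] \
            .transform("mean")
        rx = df["x"] - df.groupby(["subject_id", "win_prob"])["x"] \
            .transform("mean")
        ols = float(rx @ ry) / float(rx @ rx)
        post_sd = fit.draws.flat("beta").std()
        assert abs(res.posterior_mean - ols) < 2 * post_sd
        # and the injected raw coupling (0.2, scaled by the within-subject
        # outcome SD ~0.8) is inside the 95% HDI
        sd_j = df.groupby("subject_id")["bet"].std(ddof=1).mean()
        assert res.hdi_low < 0.2 / sd_j + 0.05
        assert res.hdi_high > 0.2 / sd_j - 0.1
        assert res.credible

    def test_shuffled_covariate_kills_coupling(self, fast_mcmc):
        df = _ancova_data(beta=0.2, seed=2)
        rng = np.random.default_rng(3)
        df["x"] = df.groupby("subject_id")["x"] \
            .transform(lambda s: rng.permutation(s.to_numpy()))
        fit = models.fit_ancova(df, "x", outcome="bet", settings=fast_mcmc,
                                seed=4)
        res = models.ancova_beta(fit)
        assert abs(res.posterior_mean) < 0.05
        assert not res.credible

    def test_mostly_missing_covariate_rejected(self, fast_mcmc):
        df = _ancova_data(seed=5)
        df.loc[df.sample(frac=0.6, random_state=0).index, "x"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            models.fit_ancova(df, "x", outcome="bet", settings=fast_mcmc)
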