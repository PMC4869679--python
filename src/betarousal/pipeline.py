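"""End-to-end orchestration: simulate -> extract -> fit -> summarize,
plus the replicated parameter-recovery suite.

The analysis sequence mirrors the study design: behavioral ANOVAs (bets,
response times), peripheral ANOVAs on the three standardized indices with
the choice-condition x chances-of-winning interaction contrast, gender
subgroup comparisons, trait regressions on peripheral reactivity, and the
trial-level ANCOVA of bet size on peripheral arousal.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import extraction, io, models, summary
from .config import CELLS, PipelineConfig
from .models import INTERACTION_WEIGHTS
from .synthetic import StudyData, simulate_study

log = logging.getLogger("betarousal")


def _setup_logging():
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Simulate a study and write all standard files to ``out_dir``."""
    _setup_logging()
    t0 = time.time()
    study = simulate_study(cfg=cfg, seed=cfg.seed)
    out = io.write_study(study, Path(out_dir))
    log.info("simulated %d subjects (seed=%d) in %.1fs -> %s",
             cfg.cohort.n_subjects, cfg.seed, time.time() - t0, out)
    return out


def extract_study(study: StudyData | None = None,
                  trials: pd.DataFrame | None = None, traces: dict = None,
                  cfg: PipelineConfig | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extraction + standardization + subject exclusions for a whole cohort.

    Returns (responses, exclusion report); responses carry the design cell
    so models can join without the trial log.
    """
    cfg = cfg or PipelineConfig()
    if study is not None:
        trials, traces = study.trials, study.traces
    parts = []
    for sid, (eda_trace, hr_trace) in traces.items():
        markers = trials.loc[trials["subject_id"] == sid,
                             ["trial_index", "onset"]] \
            if "onset" in trials.columns else eda_trace.markers
        parts.append(extraction.extract_trials(
            eda_trace, hr_trace, markers, cfg.extraction))
    responses = pd.concat(parts, ignore_index=True)
    responses = extraction.standardize(responses)
    responses, report = extraction.exclude_subjects(
        responses, cfg.extraction.exclusion_threshold)
    responses = responses.merge(
        trials[["subject_id", "trial_index", "cell", "condition",
                "win_prob", "chosen_bet", "response_time"]],
        on=["subject_id", "trial_index"], how="left")
    return responses, report


@dataclass
class AnalysisReport:
    summaries: pd.DataFrame        # all SummaryResult rows, tagged by stage
    r2: pd.DataFrame
    diagnostics: pd.DataFrame
    exclusions: pd.DataFrame
    n_eda: int
    n_hr: int
    notes: list = field(default_factory=list)
    fits: dict = field(default_factory=dict)

    def get(self, stage: str, name: str) -> dict:
        m = self.summaries[(self.summaries["stage"] == stage)
                           & (self.summaries["name"] == name)]
        if len(m) != 1:
            raise KeyError(f"no unique summary for {stage}/{name}")
        return m.iloc[0].to_dict()

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        self.r2.to_csv(out / "r2.tsv", sep="\t", index=False)
        self.diagnostics.to_csv(out / "diagnostics.tsv", sep="\t",
                                index=False)
        self.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        lines = [f"analysis ns: EDA={self.n_eda}, HR={self.n_hr}", ""]
        for row in self.summaries.itertuples(index=False):
            star = "*" if row.credible else " "
            lines.append(
                f"{star} [{row.stage}] {row.name}: {row.estimate:+.4f} "
                f"HDI95 [{row.hdi_low:+.4f}, {row.hdi_high:+.4f}] "
                f"p(tail)={row.tail_prob:.4f}")
        lines += [""] + [f"note: {n}" for n in self.notes]
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        return out


def _tag(results, stage):
    df = summary.summary_table(results)
    df.insert(0, "stage", stage)
    return df


def run_analysis(study: StudyData | None = None,
                 study_dir: str | Path | None = None,
                 cfg: PipelineConfig | None = None,
                 include_gender: bool = True,
                 keep_fits: bool = False) -> AnalysisReport:
    """The full analysis sequence on a simulated (or compatible) study."""
    _setup_logging()
    cfg = cfg or PipelineConfig()
    mc = cfg.mcmc_profile
    seed = cfg.seed + 1_000_003

    if study is None:
        if study_dir is None:
            raise ValueError("need a study or a study directory")
        trials, traces, traits = io.read_study_inputs(study_dir)
        # reconstruct onset columns from the markers
        markers = pd.concat(
            [t[0].markers.assign(subject_id=sid)
             for sid, t in traces.items()], ignore_index=True)
        trials = trials.merge(markers[["subject_id", "trial_index", "onset"]],
                              on=["subject_id", "trial_index"])
        study = StudyData(trials=trials, traces=traces, traits=traits,
                          truth=None)

    responses, report = extract_study(study=study, cfg=cfg)
    traits = study.traits.set_index("subject_id")
    n_eda = responses.dropna(subset=["z_eda"])["subject_id"].nunique()
    n_hr = responses.dropna(subset=["z_hr_acc"])["subject_id"].nunique()
    log.info("extraction done: EDA n=%d, HR n=%d (of %d)", n_eda, n_hr,
             responses["subject_id"].nunique())

    tables, r2_rows, diag_rows, notes = [], [], [], []
    fits = {}

    def note_fit(name, fit):
        diag_rows.append({"fit": name, "rhat_max": fit.rhat_max,
                          "ess_min": fit.ess_min,
                          "converged": fit.converged})
        if not fit.converged:
            notes.append(f"fit {name!r} failed the convergence gate "
                         f"(max rhat {fit.rhat_max:.3f})")
        if keep_fits:
            fits[name] = fit

    trials = study.trials
    active = trials[trials["condition"] == "active"]

    # --- behavioral ANOVAs -------------------------------------------------
    fit_bets = models.fit_anova(active, "chosen_bet", settings=mc, seed=seed)
    note_fit("bets", fit_bets)
    tables.append(_tag([
        models.contrast(fit_bets, {"A60": 1, "A40": -1}, "bet_A60-A40"),
        models.contrast(fit_bets, {"A80": 1, "A60": -1}, "bet_A80-A60"),
        models.contrast(fit_bets, {"A80": 1, "A40": -1}, "bet_A80-A40"),
    ] + [models.contrast(fit_bets, {cell: 1}, f"bet_{cell}")
         for cell in fit_bets.cells], "bets"))

    fit_rt = models.fit_anova(trials, "response_time", settings=mc,
                              seed=seed + 1)
    note_fit("rt", fit_rt)
    tables.append(_tag([
        models.contrast(fit_rt, INTERACTION_WEIGHTS, "rt_interaction"),
        # the RT decrease from 40% to 80%, active minus no-choice: the
        # positive-convention version of the same interaction
        models.contrast(fit_rt, {"A40": 1, "A80": -1, "N40": -1, "N80": 1},
                        "rt_modulation_diff"),
        models.contrast(fit_rt, {"A40": 1 / 3, "A60": 1 / 3, "A80": 1 / 3,
                                 "N40": -1 / 3, "N60": -1 / 3, "N80": -1 / 3},
                        "rt_condition_main"),
        models.contrast(fit_rt, {"A80": 1, "A40": -1}, "rt_A80-A40"),
        models.contrast(fit_rt, {"N80": 1, "N40": -1}, "rt_N80-N40"),
    ], "rt"))

    # --- peripheral ANOVAs -------------------------------------------------
    physio_fits = {}
    for i, (label, col) in enumerate((("eda", "z_eda"),
                                      ("hr_acc", "z_hr_acc"),
                                      ("hr_dec", "z_hr_dec"))):
        sub = responses.dropna(subset=[col])
        fit = models.fit_anova(sub, col, settings=mc, seed=seed + 2 + i)
        physio_fits[label] = fit
        note_fit(label, fit)
        rows = [models.contrast(fit, INTERACTION_WEIGHTS,
                                f"{label}_interaction"),
                models.contrast(fit, {"A80": 1, "A40": -1},
                                f"{label}_A80-A40"),
                models.contrast(fit, {"N80": 1, "N40": -1},
                                f"{label}_N80-N40")]
        rows += [models.contrast(fit, {cell: 1}, f"{label}_{cell}")
                 for cell in fit.cells]
        tables.append(_tag(rows, label))

    # --- gender subgroup comparisons ---------------------------------------
    if include_gender:
        genders = traits["gender"]
        resp_g = responses.join(genders, on="subject_id")
        act_g = active.join(genders, on="subject_id")
        enough = all((genders == g).sum() >= 4 for g in ("male", "female"))
        if enough:
            try:
                rows = []
                fm = models.fit_anova(act_g[act_g["gender"] == "male"],
                                      "chosen_bet", settings=mc,
                                      seed=seed + 10)
                ff = models.fit_anova(act_g[act_g["gender"] == "female"],
                                      "chosen_bet", settings=mc,
                                      seed=seed + 11)
                note_fit("bets_male", fm)
                note_fit("bets_female", ff)
                for cell in fm.cells:
                    rows.append(models.subgroup_difference(
                        fm, ff, {cell: 1}, f"bet_gender_diff_{cell}"))
                for k, (label, col) in enumerate((("eda", "z_eda"),
                                                  ("hr_acc", "z_hr_acc"),
                                                  ("hr_dec", "z_hr_dec"))):
                    sub = resp_g.dropna(subset=[col])
                    gm = models.fit_anova(sub[sub["gender"] == "male"], col,
                                          settings=mc, seed=seed + 20 + k)
                    gf = models.fit_anova(sub[sub["gender"] == "female"], col,
                                          settings=mc, seed=seed + 30 + k)
                    note_fit(f"{label}_male", gm)
                    note_fit(f"{label}_female", gf)
                    rows.append(models.subgroup_difference(
                        gm, gf, INTERACTION_WEIGHTS,
                        f"{label}_gender_interaction_diff"))
                tables.append(_tag(rows, "gender"))
            except ValueError as err:
                notes.append(f"gender subgroup analysis skipped: {err}")
        else:
            notes.append("gender subgroup analysis skipped: subgroup too "
                         "small")

    # --- trait regressions ---------------------------------------------
    preds = traits[["nonplanning", "bis", "bas"]]
    for k, (label, col) in enumerate((("eda", "z_eda"),
                                      ("hr_acc", "z_hr_acc"))):
        outcome = models.reactivity_outcome(responses, col)
        rows = []
        try:
            fit = models.fit_regression(outcome, preds, settings=mc,
                                        seed=seed + 40 + k)
            note_fit(f"reg_{label}_combined", fit)
            for trait in preds.columns:
                res = models.coefficient_summary(fit, trait)
                res.name = f"{label}_beta_{trait}"
                rows.append(res)
            r2_full = summary.bayesian_r2(fit.predictions, fit.outcome,
                                          model=f"reg_{label}_combined")
            r2_rows.append({"model": r2_full.model, "r2": r2_full.r2,
                            "r2_change": np.nan})
            for trait in preds.columns:
                single = models.fit_regression(outcome, preds[[trait]],
                                               settings=mc,
                                               seed=seed + 50 + k)
                res = models.coefficient_summary(single, trait)
                res.name = f"{label}_beta_{trait}_single"
                rows.append(res)
        except ValueError as err:
            notes.append(f"trait regression ({label}) skipped: {err}")
        tables.append(_tag(rows, f"reg_{label}"))

    # --- trial-level ANCOVA ---------------------------------------------
    merged = responses
    fit_red = None
    for k, cov in enumerate(("z_eda", "z_hr_acc")):
        sub = merged.dropna(subset=[cov])
        try:
            fit = models.fit_ancova(sub, cov, settings=mc, seed=seed + 60 + k)
            note_fit(f"ancova_{cov}", fit)
            res = models.ancova_beta(fit, f"ancova_beta_{cov}")
            tables.append(_tag([res], "ancova"))
            red = models.fit_ancova(sub, None, settings=mc,
                                    seed=seed + 70 + k)
            r2f = summary.bayesian_r2(fit.predictions, fit.outcome,
                                      model=f"ancova_{cov}")
            r2r = summary.bayesian_r2(red.predictions, red.outcome,
                                      model=f"ancova_{cov}_reduced")
            change = summary.r2_change(r2f, r2r)
            r2_rows.append({"model": r2f.model, "r2": r2f.r2,
                            "r2_change": change.r2_change})
        except ValueError as err:
            notes.append(f"ANCOVA ({cov}) skipped: {err}")

    return AnalysisReport(
        summaries=pd.concat(tables, ignore_index=True),
        r2=pd.DataFrame(r2_rows, columns=["model", "r2", "r2_change"]),
        diagnostics=pd.DataFrame(diag_rows),
        exclusions=report, n_eda=int(n_eda), n_hr=int(n_hr), notes=notes,
        fits=fits)


# ---------------------------------------------------------------------------
# replicated parameter-recovery suite
# ---------------------------------------------------------------------------

RECOVERY_TARGETS = (
    # (name, kind, truth key) — truths resolved against the generator config
    ("eda_interaction", "anova_eda", "eda"),
    ("hr_dec_interaction", "anova_hr_dec", "hr_dec"),
    ("beta_bis", "regression", "bis"),
    ("beta_bas", "regression", "bas"),
    ("beta_nonplanning", "regression", "nonplanning"),
    ("ancova_beta_eda", "ancova", "z_eda"),
    ("ancova_beta_hr_dec_null", "ancova", "z_hr_dec"),
)


def run_recovery_suite(cfg: PipelineConfig, n_replicates: int = 20,
                       seed: int | None = None) -> pd.DataFrame:
    """Replicated simulate->analyze cycles: bias, RMSE, HDI coverage, and
    credible-flag rates for the key generative parameters.

    Injected (non-null) targets: the EDA choice-condition x win-probability
    interaction, the BIS/BAS weights on HR-acceleration reactivity, and the
    EDA->bet arousal coupling.  Null targets: the HR-deceleration
    interaction, the nonplanning weight, and an uncoupled-covariate ANCOVA.
    """
    _setup_logging()
    if n_replicates < 10:
        raise ValueError("recovery suite needs at least 10 replicates")
    if seed is None:
        seed = cfg.seed
    mc = cfg.mcmc_profile
    truths = {
        "eda_interaction": None,   # filled from the study's ground truth
        "hr_dec_interaction": None,
        "beta_bis": cfg.physio.bis_weight_hr_acc,
        "beta_bas": cfg.physio.bas_weight_hr_acc,
        "beta_nonplanning": 0.0,
        "ancova_beta_eda": cfg.behavior.arousal_coupling,
        "ancova_beta_hr_dec_null": 0.0,
    }
    records = []
    seqs = np.random.SeedSequence(seed).spawn(n_replicates)
    for r, seq in enumerate(seqs):
        rep_seed = int(seq.generate_state(1)[0] % (2 ** 31))
        study = simulate_study(cfg=cfg, seed=rep_seed)
        truths["eda_interaction"] = study.truth.interaction_effect("eda")
        truths["hr_dec_interaction"] = study.truth.interaction_effect(
            "hr_dec")
        responses, _ = extract_study(study=study, cfg=cfg)
        traits = study.traits.set_index("subject_id")

        results = {}
        for label, col in (("eda", "z_eda"), ("hr_dec", "z_hr_dec")):
            sub = responses.dropna(subset=[col])
            fit = models.fit_anova(sub, col, settings=mc, seed=rep_seed + 1)
            results[f"{label}_interaction"] = models.contrast(
                fit, INTERACTION_WEIGHTS, f"{label}_interaction")
        outcome = models.reactivity_outcome(responses, "z_hr_acc")
        reg = models.fit_regression(
            outcome, traits[["nonplanning", "bis", "bas"]], settings=mc,
            seed=rep_seed + 2)
        for trait in ("bis", "bas", "nonplanning"):
            results[f"beta_{trait}"] = models.coefficient_summary(reg, trait)
        for label, cov in (("ancova_beta_eda", "z_eda"),
                           ("ancova_beta_hr_dec_null", "z_hr_dec")):
            sub = responses.dropna(subset=[cov])
            fit = models.fit_ancova(sub, cov, settings=mc, seed=rep_seed + 3)
            results[label] = models.ancova_beta(fit, label)

        for name, res in results.items():
            truth = truths[name]
            records.append({
                "replicate": r, "parameter": name, "truth": truth,
                "estimate": res.posterior_mean,
                "hdi_low": res.hdi_low, "hdi_high": res.hdi_high,
                "covered": bool(res.hdi_low <= truth <= res.hdi_high),
                "credible": res.credible,
            })
        log.info("recovery replicate %d/%d done", r + 1, n_replicates)

    df = pd.DataFrame(records)
    agg = df.groupby("parameter").apply(lambda g: pd.Series({
        "truth": g["truth"].mean(),
        "mean_estimate": g["estimate"].mean(),
        "bias": (g["estimate"] - g["truth"]).mean(),
        "rmse": float(np.sqrt(((g["estimate"] - g["truth"]) ** 2).mean())),
        "mc_se": g["estimate"].std(ddof=1) / np.sqrt(len(g)),
        "coverage": g["covered"].mean(),
        "credible_rate": g["credible"].mean(),
        "n_replicates": len(g),
    }), include_groups=False).reset_index()
    return agg
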