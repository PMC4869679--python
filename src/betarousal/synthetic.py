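"""Synthetic Roulette Betting Task studies with known ground truth.

A session has 90 trials — 15 in each of the six design cells (active vs
no-choice crossed with 40/60/80% chances of winning) — split into three
blocks of 30.  The simulated agent bets by a softmax choice rule over the
three bet options (10/50/90 points) whose utility is linear in the chances
of winning plus a subject-level betting bias and a trial-level arousal
term; response times fall with the chances of winning, more steeply on
active-choice trials; outcomes are Bernoulli in the stated win probability.

Peripheral traces are composed of a slow tonic component plus per-trial
event-locked kernels: a skin-conductance response (difference of
exponentials, ~1 s latency, peaking inside the 2-7 s extraction window)
and a biphasic heart-rate kernel (an early deceleration lobe inside 0-3 s
and a rebound acceleration lobe inside 2-6 s).  Every trial's injected
amplitude is recorded so extraction can be validated exactly: each kernel
is normalized by its own on-grid extremum inside the extraction window,
making the noiseless round-trip exact to machine precision.

Ground-truth effect structure is specified on the within-subject z scale
(the scale on which the models operate): per-cell mean response deviations,
trait-linked subject reactivity, and a trial-level arousal state that
couples bet size to the EDA response with a configurable regression weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (BET_OPTIONS, CELLS, WIN_PROBS, BehaviorConfig,
                     CohortConfig, PhysioConfig, PipelineConfig, SignalConfig)
from .extraction import SignalTrace

_ACTIVE_PATTERN = np.array([-1.0, 0.0, 1.0, 0.0, 0.0, 0.0])  # A40 A60 A80 ...
_BET_X = np.array([-1.0, 0.0, 1.0])  # standardized bet levels for 10/50/90


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def make_schedule(seed: int | np.random.Generator) -> pd.DataFrame:
    """90-trial session schedule: 15 trials per cell, pseudo-random order
    within three blocks of 30 (5 trials per cell per block)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rows = []
    # balanced dictated amounts for no-choice cells: 5 x {10,50,90} per cell
    dictated: dict[str, list] = {}
    for cell in CELLS:
        if cell.startswith("N"):
            amounts = [b for b in BET_OPTIONS for _ in range(5)]
            rng.shuffle(amounts)
            dictated[cell] = amounts
    counters = {cell: 0 for cell in CELLS}
    trial_index = 0
    for block in (1, 2, 3):
        cells = [c for c in CELLS for _ in range(5)]
        rng.shuffle(cells)
        for cell in cells:
            condition = "active" if cell.startswith("A") else "no_choice"
            win_prob = int(cell[1:]) / 100.0
            if condition == "active":
                opts = BET_OPTIONS
            else:
                amt = dictated[cell][counters[cell]]
                opts = (amt, amt, amt)
            counters[cell] += 1
            rows.append({"block": block, "trial_index": trial_index,
                         "cell": cell, "condition": condition,
                         "win_prob": win_prob,
                         "bet_opt1": opts[0], "bet_opt2": opts[1],
                         "bet_opt3": opts[2]})
            trial_index += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiles and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    subject_id: str
    gender: str                 # "male" / "female"
    bis: int
    bas: int
    nonplanning: int
    latent_reactivity: float    # HR-acceleration reactivity deviation (z)
    latent_bet_bias: float      # betting-tendency term (utility units)


@dataclass
class GroundTruth:
    """Everything injected by the generator, for parameter-recovery checks."""
    cell_means: dict            # channel -> (6,) population z-scale means
    subject_cell_means: dict    # channel -> DataFrame (subject x 6 cells)
    trial_truth: pd.DataFrame   # injected per-trial amplitudes + components
    arousal_coupling: float     # z-bet per z-EDA regression weight
    utility_delta: float        # calibrated softmax perturbation
    rt_cell_means: dict         # cell -> expected RT (ms)
    expected_bets: dict         # win_prob -> expected active bet (points)
    trait_weights: dict         # channel -> (bis, bas) weights

    def interaction_effect(self, channel: str) -> float:
        m = self.cell_means[channel]
        return float((m[2] - m[0]) - (m[5] - m[3]))


def _truncated_normal_int(rng, mean, sd, lo, hi, size):
    out = np.empty(size, dtype=int)
    for i in range(size):
        while True:
            v = int(round(rng.normal(mean, sd)))
            if lo <= v <= hi:
                out[i] = v
                break
    return out


def make_cohort(cfg: CohortConfig, physio: PhysioConfig,
                behavior: BehaviorConfig,
                rng: np.random.Generator) -> list[SubjectProfile]:
    """Subject profiles with trait scores inside the instrument ranges and
    trait-linked latent HR-acceleration reactivity."""
    n = cfg.n_subjects
    genders = np.where(rng.random(n) < cfg.p_male, "male", "female")
    profiles = []
    pop_bis = cfg.p_male * cfg.bis["mean_male"] \
        + (1 - cfg.p_male) * cfg.bis["mean_female"]
    pop_bas = cfg.p_male * cfg.bas["mean_male"] \
        + (1 - cfg.p_male) * cfg.bas["mean_female"]
    for i in range(n):
        g = genders[i]
        suffix = "male" if g == "male" else "female"
        tr = {}
        for trait, spec in (("nonplanning", cfg.nonplanning),
                            ("bis", cfg.bis), ("bas", cfg.bas)):
            tr[trait] = int(_truncated_normal_int(
                rng, spec[f"mean_{suffix}"], spec[f"sd_{suffix}"],
                spec["lo"], spec["hi"], 1)[0])
        react = (physio.bis_weight_hr_acc * (tr["bis"] - pop_bis)
                 + physio.bas_weight_hr_acc * (tr["bas"] - pop_bas)
                 + rng.normal(0.0, physio.reactivity_sd_hr_acc))
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:03d}", gender=str(g),
            bis=tr["bis"], bas=tr["bas"], nonplanning=tr["nonplanning"],
            latent_reactivity=float(react),
            latent_bet_bias=float(rng.normal(0.0, behavior.bet_bias_sd))))
    return profiles


# ---------------------------------------------------------------------------
# softmax choice rule and its moments
# ---------------------------------------------------------------------------

def bet_probabilities(theta: float) -> np.ndarray:
    """Softmax over the three bet options with utility ``theta * x``,
    x = (-1, 0, +1) for bets (10, 50, 90)."""
    u = theta * _BET_X
    e = np.exp(u - u.max())
    return e / e.sum()


def expected_bet(theta: float) -> float:
    return float(bet_probabilities(theta) @ np.asarray(BET_OPTIONS, float))


def bet_variance(theta: float) -> float:
    p = bet_probabilities(theta)
    b = np.asarray(BET_OPTIONS, float)
    m = p @ b
    return float(p @ (b - m) ** 2)


def _theta_of_p(behavior: BehaviorConfig, win_prob: float) -> float:
    return behavior.bet_prob_slope * (win_prob - 0.60) / 0.20


def calibrate_utility_delta(behavior: BehaviorConfig,
                            physio: PhysioConfig) -> float:
    """Softmax perturbation per unit arousal that yields the configured
    ``arousal_coupling`` (z-bet on z-EDA regression weight).

    Delta-method linearization of the choice rule: within a win-probability
    cell, dE[bet]/d(theta) = g'(theta); the within-subject bet SD pools the
    between-cell spread and the within-cell choice variance.
    """
    thetas = np.array([_theta_of_p(behavior, p) for p in WIN_PROBS])
    means = np.array([expected_bet(t) for t in thetas])
    wvars = np.array([bet_variance(t) for t in thetas])
    s_bet = np.sqrt(np.var(means) + np.mean(wvars))
    eps = 1e-5
    gprime = np.mean([(expected_bet(t + eps) - expected_bet(t - eps))
                      / (2 * eps) for t in thetas])
    s_trial = np.sqrt(max(0.05, 1.0 - np.var(np.asarray(
        physio.eda_cell_means))))
    if gprime <= 0:
        return 0.0
    return float(behavior.arousal_coupling * s_bet * s_trial / gprime)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _validate_behavior(behavior: BehaviorConfig) -> None:
    for name in ("bet_prob_slope", "bet_bias_sd", "arousal_coupling",
                 "rt_subject_sd", "rt_noise_sd"):
        v = getattr(behavior, name)
        if not np.isfinite(v):
            raise ValueError(f"behavior parameter {name} must be finite")
    for name in ("bet_bias_sd", "rt_subject_sd", "rt_noise_sd"):
        if getattr(behavior, name) < 0:
            raise ValueError(f"behavior parameter {name} must be >= 0")


def simulate_behavior(schedule: pd.DataFrame, profile: SubjectProfile,
                      behavior: BehaviorConfig, physio: PhysioConfig,
                      rng: np.random.Generator,
                      utility_delta: float | None = None) -> pd.DataFrame:
    """Bets, response times, outcomes, and the latent trial arousal state.

    The returned frame carries the hidden ``arousal`` column (ground
    truth); the public trial log drops it.
    """
    _validate_behavior(behavior)
    if utility_delta is None:
        utility_delta = calibrate_utility_delta(behavior, physio)
    df = schedule.copy()
    n = len(df)
    arousal = rng.standard_normal(n)
    rt_subject = rng.normal(0.0, behavior.rt_subject_sd)
    active = (df["condition"] == "active").to_numpy()
    x_p = (df["win_prob"].to_numpy() - 0.60) / 0.20

    # softmax choice by inverse CDF (vectorized over active trials)
    theta = (behavior.bet_prob_slope * x_p[active] + profile.latent_bet_bias
             + utility_delta * arousal[active])
    u = np.exp(np.outer(theta, _BET_X)
               - np.abs(theta)[:, None])  # stabilized
    probs = u / u.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    draws = rng.random(active.sum())
    choice = (draws[:, None] > cum).sum(axis=1)
    bets = df["bet_opt1"].to_numpy().astype(int).copy()
    bets[active] = np.asarray(BET_OPTIONS, dtype=int)[choice]

    rt_mean = np.where(
        active,
        behavior.rt_intercept_active + behavior.rt_slope_active * x_p,
        behavior.rt_intercept_nochoice + behavior.rt_slope_nochoice * x_p)
    rts = np.maximum(behavior.rt_floor,
                     rt_mean + rt_subject
                     + rng.normal(0.0, behavior.rt_noise_sd, size=n))
    wins = rng.random(n) < df["win_prob"].to_numpy()
    df["subject_id"] = profile.subject_id
    df["chosen_bet"] = bets
    df["response_time"] = np.round(rts, 1)
    df["outcome"] = np.where(wins, "win", "loss")
    df["points_delta"] = np.where(wins, bets, -bets)
    df["arousal"] = arousal
    return df


def session_timeline(trials: pd.DataFrame, signal: SignalConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Wheel-onset / response / outcome times; inter-trial gaps >= 8 s."""
    df = trials.copy()
    t = signal.lead_in
    onsets, responses, outcomes = [], [], []
    for rt_ms in df["response_time"].to_numpy():
        onset = t
        response = onset + rt_ms / 1000.0
        spin = rng.uniform(*signal.spin_range)
        outcome = response + spin
        onsets.append(onset)
        responses.append(response)
        outcomes.append(outcome)
        t = outcome + signal.feedback_duration + rng.uniform(*signal.iti_range)
    df["onset"] = onsets
    df["response_s"] = responses
    df["outcome_s"] = outcomes
    return df


# ---------------------------------------------------------------------------
# physiological traces
# ---------------------------------------------------------------------------

def _scr_shape(lag: np.ndarray, signal: SignalConfig) -> np.ndarray:
    """Difference-of-exponentials SCR kernel; compact support with a linear
    taper to exactly zero at ``scr_support`` seconds."""
    t = lag - signal.scr_latency
    shape = np.where(
        t > 0,
        np.exp(-np.maximum(t, 0) / signal.scr_decay_tau)
        - np.exp(-np.maximum(t, 0) / signal.scr_rise_tau),
        0.0)
    taper = np.clip((signal.scr_support - lag) / 2.0, 0.0, 1.0)
    return shape * taper


def _lobe_shape(lag: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Raised-cosine lobe: zero at the edges, one at the center."""
    a, b = window
    inside = (lag > a) & (lag < b)
    out = np.zeros_like(lag)
    out[inside] = np.sin(np.pi * (lag[inside] - a) / (b - a)) ** 2
    return out


def _add_kernels(values: np.ndarray, fs: float, onsets: np.ndarray,
                 amps: np.ndarray, shape_fn, support: float,
                 norm_window: tuple[float, float],
                 minimum: bool = False) -> None:
    """Add one amplitude-normalized kernel per trial, in place.

    Each kernel is scaled so its on-grid extremum inside ``norm_window``
    (relative to onset) equals the injected amplitude exactly.
    """
    n = len(values)
    for onset, amp in zip(onsets, amps):
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = min(n - 1, int(np.floor((onset + support) * fs + 1e-9)))
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1 + 1)
        lag = idx / fs - onset
        shape = shape_fn(lag)
        in_win = (lag >= norm_window[0] - 1e-12) & \
                 (lag <= norm_window[1] + 1e-12)
        peak = np.max(shape[in_win]) if np.any(in_win) else np.max(shape)
        if peak <= 0:
            continue
        values[idx] += (amp / peak) * shape


def simulate_signals(trials: pd.DataFrame, trial_truth: pd.DataFrame,
                     signal: SignalConfig, rng: np.random.Generator,
                     subject_id: str, tonic_eda: float, baseline_hr: float,
                     ) -> tuple[SignalTrace, SignalTrace]:
    """EDA and HR traces with the per-trial injected amplitudes from
    ``trial_truth`` (columns eda_amp, hr_dec_amp, hr_acc_amp)."""
    onsets = trials["onset"].to_numpy()
    duration = float(trials["outcome_s"].iloc[-1]) + signal.tail
    markers = trials[["trial_index", "onset", "response_s", "outcome_s"]] \
        .rename(columns={"response_s": "response", "outcome_s": "outcome"})

    # ---- EDA ----
    n_eda = int(np.floor(duration * signal.eda_fs)) + 1
    t_eda = np.arange(n_eda) / signal.eda_fs
    eda = np.full(n_eda, tonic_eda)
    if not signal.noiseless:
        ph = rng.uniform(0, 2 * np.pi, size=2)
        eda += signal.eda_drift_amp * np.sin(2 * np.pi * t_eda / 413.0 + ph[0])
        eda += 0.5 * signal.eda_drift_amp * np.sin(
            2 * np.pi * t_eda / 147.0 + ph[1])
    _add_kernels(eda, signal.eda_fs, onsets,
                 trial_truth["eda_amp"].to_numpy(),
                 lambda lag: _scr_shape(lag, signal), signal.scr_support,
                 norm_window=(2.0, 7.0))
    if not signal.noiseless and signal.eda_noise_sd > 0:
        eda += rng.normal(0.0, signal.eda_noise_sd, size=n_eda)
    np.maximum(eda, 0.0, out=eda)

    # ---- HR ----
    n_hr = int(np.floor(duration * signal.hr_fs)) + 1
    t_hr = np.arange(n_hr) / signal.hr_fs
    hr = np.full(n_hr, baseline_hr)
    if not signal.noiseless:
        ph = rng.uniform(0, 2 * np.pi, size=2)
        hr += signal.hr_wave_amp * np.sin(2 * np.pi * 0.15 * t_hr + ph[0])
        hr += 0.5 * signal.hr_wave_amp * np.sin(
            2 * np.pi * t_hr / 90.0 + ph[1])
    _add_kernels(hr, signal.hr_fs, onsets,
                 trial_truth["hr_dec_amp"].to_numpy(),
                 lambda lag: _lobe_shape(lag, signal.hr_dip_window),
                 signal.hr_dip_window[1],
                 norm_window=(0.0, 3.0))
    _add_kernels(hr, signal.hr_fs, onsets,
                 trial_truth["hr_acc_amp"].to_numpy(),
                 lambda lag: _lobe_shape(lag, signal.hr_rebound_window),
                 signal.hr_rebound_window[1],
                 norm_window=(2.0, 6.0))
    if not signal.noiseless and signal.hr_noise_sd > 0:
        hr += rng.normal(0.0, signal.hr_noise_sd, size=n_hr)

    eda_trace = SignalTrace(subject_id=subject_id, channel="EDA",
                            sampling_rate=signal.eda_fs, t0=0.0,
                            values=eda, markers=markers)
    hr_trace = SignalTrace(subject_id=subject_id, channel="HR",
                           sampling_rate=signal.hr_fs, t0=0.0,
                           values=hr, markers=markers)
    return eda_trace, hr_trace


def _corrupt(trace: SignalTrace, trials: pd.DataFrame, fraction: float,
             rng: np.random.Generator) -> None:
    """Flatline artifact spans over a random subset of trials (emulating
    electrode/recording failures); covers baseline + response windows."""
    n_bad = int(np.ceil(fraction * len(trials)))
    bad = rng.choice(len(trials), size=n_bad, replace=False)
    fs = trace.sampling_rate
    for k in bad:
        onset = float(trials["onset"].iloc[k])
        i0 = max(0, int((onset - 1.5) * fs))
        i1 = min(len(trace.values) - 1, int((onset + 8.0) * fs))
        trace.values[i0: i1 + 1] = trace.values[i0]


# ---------------------------------------------------------------------------
# per-trial injected amplitudes
# ---------------------------------------------------------------------------

def _subject_cell_means(physio: PhysioConfig, react_eda: float,
                        react_acc: float, react_dec: float) -> dict:
    out = {}
    for channel, base, react in (("eda", physio.eda_cell_means, react_eda),
                                 ("hr_acc", physio.hr_acc_cell_means,
                                  react_acc),
                                 ("hr_dec", physio.hr_dec_cell_means,
                                  react_dec)):
        out[channel] = np.asarray(base, float) + 0.5 * react * _ACTIVE_PATTERN
    return out


def make_trial_truth(trials: pd.DataFrame, physio: PhysioConfig,
                     cell_means: dict, rng: np.random.Generator
                     ) -> pd.DataFrame:
    """Injected raw amplitudes per trial, built from z-scale cell means plus
    trial fluctuation whose variance tops the within-subject total up to 1."""
    cell_idx = np.array([CELLS.index(c) for c in trials["cell"]])
    a = trials["arousal"].to_numpy()
    n = len(trials)

    def s_trial(means):
        return np.sqrt(max(0.05, 1.0 - float(np.mean(means ** 2))))

    z_eda = cell_means["eda"][cell_idx] + s_trial(cell_means["eda"]) * a
    mix = physio.hr_acc_arousal_mix
    z_acc = cell_means["hr_acc"][cell_idx] + s_trial(cell_means["hr_acc"]) * (
        mix * a + np.sqrt(1.0 - mix ** 2) * rng.standard_normal(n))
    z_dec = cell_means["hr_dec"][cell_idx] \
        + s_trial(cell_means["hr_dec"]) * rng.standard_normal(n)

    # peak-minus-baseline measures cannot represent amplitudes of the wrong
    # sign; clip the rare tail draws and record the clipped value as truth
    eda_amp = np.maximum(physio.eda_amp_base + physio.eda_amp_scale * z_eda,
                         0.0)
    acc_amp = np.maximum(physio.hr_acc_base + physio.hr_acc_scale * z_acc,
                         0.0)
    dec_amp = np.minimum(physio.hr_dec_base + physio.hr_dec_scale * z_dec,
                         0.0)
    return pd.DataFrame({
        "subject_id": trials["subject_id"].to_numpy(),
        "trial_index": trials["trial_index"].to_numpy(),
        "cell": trials["cell"].to_numpy(),
        "z_eda_true": (eda_amp - physio.eda_amp_base) / physio.eda_amp_scale,
        "z_hr_acc_true": (acc_amp - physio.hr_acc_base) / physio.hr_acc_scale,
        "z_hr_dec_true": (dec_amp - physio.hr_dec_base) / physio.hr_dec_scale,
        "eda_amp": eda_amp, "hr_acc_amp": acc_amp, "hr_dec_amp": dec_amp,
        "arousal": a,
    })


# ---------------------------------------------------------------------------
# whole-study wrapper
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    trials: pd.DataFrame                  # all subjects' trial logs
    traces: dict                          # subject_id -> (eda, hr) traces
    traits: pd.DataFrame
    truth: GroundTruth
    seed: int = 0
    corrupted: dict = field(default_factory=lambda: {"EDA": [], "HR": []})


def simulate_study(n_subjects: int | None = None,
                   cfg: PipelineConfig | None = None,
                   seed: int | None = None) -> StudyData:
    """Simulate a full cohort: trial logs, traces, traits, ground truth.

    Deterministic given the seed; all randomness flows from one master
    ``SeedSequence`` via named substreams (cohort, then per-subject
    schedule / behavior / signals).
    """
    cfg = cfg or PipelineConfig()
    if n_subjects is None:
        n_subjects = cfg.cohort.n_subjects
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if seed is None:
        seed = cfg.seed

    root = np.random.SeedSequence(seed)
    cohort_seq, subjects_seq = root.spawn(2)
    rng_cohort = np.random.default_rng(cohort_seq)

    cohort_cfg = cfg.cohort
    profiles = make_cohort(
        CohortConfig(**{**cohort_cfg.__dict__, "n_subjects": n_subjects}),
        cfg.physio, cfg.behavior, rng_cohort)
    delta = calibrate_utility_delta(cfg.behavior, cfg.physio)

    # disjoint corrupted subject sets per channel
    order = rng_cohort.permutation(n_subjects)
    n_eda_bad = min(cohort_cfg.n_corrupt_eda, n_subjects)
    n_hr_bad = min(cohort_cfg.n_corrupt_hr, max(0, n_subjects - n_eda_bad))
    eda_bad = {profiles[i].subject_id for i in order[:n_eda_bad]}
    hr_bad = {profiles[i].subject_id
              for i in order[n_eda_bad:n_eda_bad + n_hr_bad]}

    all_trials, all_truth = [], []
    traces = {}
    subj_means: dict[str, list] = {"eda": [], "hr_acc": [], "hr_dec": []}
    seqs = subjects_seq.spawn(n_subjects)
    for prof, seq in zip(profiles, seqs):
        s_sched, s_beh, s_sig, s_react = seq.spawn(4)
        rng_r = np.random.default_rng(s_react)
        react_eda = rng_r.normal(0.0, cfg.physio.reactivity_sd_eda)
        react_dec = rng_r.normal(0.0, cfg.physio.reactivity_sd_hr_dec)
        cell_means = _subject_cell_means(
            cfg.physio, react_eda, prof.latent_reactivity, react_dec)
        for ch in subj_means:
            subj_means[ch].append(cell_means[ch])

        schedule = make_schedule(np.random.default_rng(s_sched))
        rng_b = np.random.default_rng(s_beh)
        trials = simulate_behavior(schedule, prof, cfg.behavior, cfg.physio,
                                   rng_b, utility_delta=delta)
        rng_s = np.random.default_rng(s_sig)
        trials = session_timeline(trials, cfg.signal, rng_s)
        truth = make_trial_truth(trials, cfg.physio, cell_means, rng_s)
        tonic = max(2.0, rng_s.normal(cfg.signal.eda_tonic_mean,
                                      cfg.signal.eda_tonic_sd))
        hr0 = rng_s.normal(cfg.signal.hr_baseline_mean,
                           cfg.signal.hr_baseline_sd)
        eda_trace, hr_trace = simulate_signals(
            trials, truth, cfg.signal, rng_s, prof.subject_id, tonic, hr0)
        if prof.subject_id in eda_bad:
            _corrupt(eda_trace, trials, cohort_cfg.corrupt_fraction, rng_s)
        if prof.subject_id in hr_bad:
            _corrupt(hr_trace, trials, cohort_cfg.corrupt_fraction, rng_s)
        traces[prof.subject_id] = (eda_trace, hr_trace)
        all_trials.append(trials)
        all_truth.append(truth)

    traits = pd.DataFrame([{
        "subject_id": p.subject_id, "gender": p.gender, "bis": p.bis,
        "bas": p.bas, "nonplanning": p.nonplanning,
        "latent_reactivity": p.latent_reactivity,
        "latent_bet_bias": p.latent_bet_bias} for p in profiles])

    ids = [p.subject_id for p in profiles]
    truth = GroundTruth(
        cell_means={ch: np.asarray(getattr(cfg.physio, f"{ch}_cell_means"),
                                   float)
                    for ch in ("eda", "hr_acc", "hr_dec")},
        subject_cell_means={ch: pd.DataFrame(np.vstack(v), index=ids,
                                             columns=list(CELLS))
                            for ch, v in subj_means.items()},
        trial_truth=pd.concat(all_truth, ignore_index=True),
        arousal_coupling=cfg.behavior.arousal_coupling,
        utility_delta=delta,
        rt_cell_means={
            cell: (cfg.behavior.rt_intercept_active
                   + cfg.behavior.rt_slope_active * x
                   if cell.startswith("A") else
                   cfg.behavior.rt_intercept_nochoice
                   + cfg.behavior.rt_slope_nochoice * x)
            for cell, x in zip(CELLS, [-1, 0, 1, -1, 0, 1])},
        expected_bets={p: expected_bet(_theta_of_p(cfg.behavior, p))
                       for p in WIN_PROBS},
        trait_weights={"hr_acc": (cfg.physio.bis_weight_hr_acc,
                                  cfg.physio.bas_weight_hr_acc),
                       "eda": (0.0, 0.0), "hr_dec": (0.0, 0.0)},
    )
    return StudyData(trials=pd.concat(all_trials, ignore_index=True),
                     traces=traces, traits=traits, truth=truth, seed=seed,
                     corrupted={"EDA": sorted(eda_bad),
                                "HR": sorted(hr_bad)})
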