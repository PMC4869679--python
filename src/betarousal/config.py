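"""Configuration objects for the simulation / extraction / modelling pipeline.

All tunable parameters live in plain dataclasses with study-scale defaults,
and can be overridden from a single YAML file (see :func:`load_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

#: the six design cells, canonical order
CELLS = ("A40", "A60", "A80", "N40", "N60", "N80")
WIN_PROBS = (0.40, 0.60, 0.80)
BET_OPTIONS = (10, 50, 90)


@dataclass
class BehaviorConfig:
    """Parameters of the simulated betting agent."""

    #: softmax-utility slope on the (win_prob - 0.6)/0.2 axis; positive values
    #: make the expected bet strictly increasing in the chances of winning
    bet_prob_slope: float = 1.5
    #: SD of the subject-level betting-tendency term (utility units)
    bet_bias_sd: float = 0.4
    #: linear effect of the z-scored trial EDA response on the z-scored bet;
    #: the utility perturbation is calibrated internally to hit this value
    arousal_coupling: float = 0.04
    #: response-time structure (ms): intercepts at the 60% level and slopes
    #: per win-probability step, separately for the two choice conditions
    rt_intercept_active: float = 2500.0
    rt_intercept_nochoice: float = 1800.0
    rt_slope_active: float = -550.0
    rt_slope_nochoice: float = -212.0
    rt_subject_sd: float = 300.0
    rt_noise_sd: float = 450.0
    rt_floor: float = 200.0


@dataclass
class PhysioConfig:
    """Ground-truth response-amplitude structure, on the within-subject
    z scale (one unit = one within-subject SD of the extracted response)."""

    # per-cell mean deviations, order A40 A60 A80 N40 N60 N80; sum to zero
    eda_cell_means: tuple = (-0.12, 0.0, 0.12, 0.05, 0.0, -0.05)
    hr_acc_cell_means: tuple = (-0.17, 0.0, 0.17, 0.0, 0.0, 0.0)
    hr_dec_cell_means: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    # raw scale of one z unit, and the grand-mean raw amplitude
    eda_amp_base: float = 0.40     # micro-Siemens
    eda_amp_scale: float = 0.10
    hr_acc_base: float = 3.0       # bpm
    hr_acc_scale: float = 1.2
    hr_dec_base: float = -4.0      # bpm (negative = deceleration)
    hr_dec_scale: float = 1.2
    # subject reactivity = deviation of the (A80 - A40) z difference.
    # HR acceleration reactivity is trait linked (per point of BIS / BAS);
    # EDA reactivity is heterogeneous but trait free.
    bis_weight_hr_acc: float = 0.047
    bas_weight_hr_acc: float = -0.03
    reactivity_sd_hr_acc: float = 0.37
    reactivity_sd_eda: float = 0.35
    reactivity_sd_hr_dec: float = 0.30
    #: correlation of the shared trial arousal state with the HR-acc trial
    #: fluctuation (EDA is fully coupled); 0.75 makes the implied
    #: HR-acc -> bet coupling 0.75x the EDA coupling (0.03 vs 0.04)
    hr_acc_arousal_mix: float = 0.75


@dataclass
class SignalConfig:
    """Trace synthesis: sampling rates, kernels, noise, session timing."""

    eda_fs: float = 100.0
    hr_fs: float = 10.0
    eda_tonic_mean: float = 6.0    # micro-Siemens
    eda_tonic_sd: float = 1.5
    eda_drift_amp: float = 0.2     # slow sinusoidal tonic drift
    eda_noise_sd: float = 0.01
    hr_baseline_mean: float = 70.0  # bpm
    hr_baseline_sd: float = 8.0
    hr_wave_amp: float = 0.3       # slow respiratory-like oscillation
    hr_noise_sd: float = 0.2
    # SCR kernel: difference of exponentials, 1 s onset latency
    scr_rise_tau: float = 0.75
    scr_decay_tau: float = 2.0
    scr_latency: float = 1.0
    scr_support: float = 14.0      # hard-tapered to zero by this lag
    # HR kernel: two half-cosine lobes with disjoint supports
    hr_dip_window: tuple = (0.2, 2.6)
    hr_rebound_window: tuple = (2.6, 6.0)
    # session timing (seconds)
    spin_range: tuple = (7.0, 8.5)
    feedback_duration: float = 2.0
    iti_range: tuple = (8.0, 10.0)
    lead_in: float = 30.0
    tail: float = 15.0
    noiseless: bool = False        # zero out noise AND tonic drift/waves


@dataclass
class CohortConfig:
    """Cohort composition and trait-score generation."""

    n_subjects: int = 68
    p_male: float = 25.0 / 68.0
    # trait means / SDs (male, female) and instrument ranges
    nonplanning: dict = field(default_factory=lambda: dict(
        mean_male=22.0, mean_female=22.1, sd_male=4.1, sd_female=5.6,
        lo=13, hi=35))
    bis: dict = field(default_factory=lambda: dict(
        mean_male=19.9, mean_female=21.8, sd_male=3.2, sd_female=3.7,
        lo=10, hi=27))
    bas: dict = field(default_factory=lambda: dict(
        mean_male=39.6, mean_female=39.4, sd_male=5.0, sd_female=5.5,
        lo=22, hi=50))
    #: number of subjects with flatline artifact corruption per channel
    n_corrupt_eda: int = 4
    n_corrupt_hr: int = 5
    #: fraction of a corrupted subject's trials covered by artifacts
    corrupt_fraction: float = 0.35


@dataclass
class ExtractionConfig:
    baseline_statistic: str = "mean"   # or "last"
    exclusion_threshold: float = 0.25  # max tolerated invalid-trial fraction
    flatline_check: bool = True
    flatline_eps: float = 1e-9


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_iter: int = 25_000   # retained draws per chain (4 x 25,000 = 100,000)
    burn_in: int = 5_000
    rhat_gate: float = 1.1

    def reduced(self) -> "McmcConfig":
        """Desk-scale profile for replicated fits."""
        return McmcConfig(n_chains=self.n_chains, n_iter=2_500, burn_in=1_000,
                          rhat_gate=self.rhat_gate)


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    physio: PhysioConfig = field(default_factory=PhysioConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    paper_scale: bool = False  # False: reduced MCMC profile (4 x 2,500)

    @property
    def mcmc_profile(self) -> McmcConfig:
        return self.mcmc if self.paper_scale else self.mcmc.reduced()

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "cohort": CohortConfig, "behavior": BehaviorConfig, "physio": PhysioConfig,
    "signal": SignalConfig, "extraction": ExtractionConfig, "mcmc": McmcConfig,
}


def _build(cls, data: dict[str, Any]):
    obj = cls()
    for key, val in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown {cls.__name__} option: {key!r}")
        current = getattr(obj, key)
        if isinstance(current, tuple) and isinstance(val, list):
            val = tuple(val)
        setattr(obj, key, val)
    return obj


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file and/or a dict."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                data.setdefault(key, {}).update(val)
            else:
                data[key] = val
    cfg = PipelineConfig()
    for key, val in data.items():
        if key in _SECTIONS:
            setattr(cfg, key, _build(_SECTIONS[key], val))
        elif hasattr(cfg, key):
            setattr(cfg, key, val)
        else:
            raise KeyError(f"unknown config section: {key!r}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
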