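"""Event-locked extraction of per-trial peripheral responses.

For every trial, responses are referenced to the wheel onset:

* baseline — mean of the 1-s window immediately preceding onset,
  half-open ``[onset-1, onset)``;
* EDA response — maximum in the closed window ``[onset+2, onset+7]``
  minus baseline (micro-Siemens);
* HR deceleration — minimum in ``[onset, onset+3]`` minus baseline (bpm,
  typically negative);
* HR acceleration — maximum in ``[onset+2, onset+6]`` minus baseline (bpm).

The EDA window ends at 7 s while the HR acceleration window ends at 6 s;
the asymmetry is deliberate and matches the extraction protocol this
module implements.  The two HR windows overlap and are computed
independently.  Raw responses are then z-scored within participant over
valid trials (sample SD, n-1), pooling all six design cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ExtractionConfig

_EPS = 1e-9

EDA_WINDOW = (2.0, 7.0)
HR_DEC_WINDOW = (0.0, 3.0)
HR_ACC_WINDOW = (2.0, 6.0)
BASELINE_SPAN = 1.0


@dataclass
class SignalTrace:
    """Uniformly sampled physiological channel with event markers."""
    subject_id: str
    channel: str                 # "EDA" or "HR"
    sampling_rate: float         # Hz
    t0: float                    # time of first sample, seconds
    values: np.ndarray
    markers: pd.DataFrame | None = None  # trial_index, onset, response, outcome

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.sampling_rate < 4.0:
            raise ValueError(
                "sampling rate below 4 Hz cannot resolve the extraction "
                "windows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.sampling_rate

    def time_of(self, idx: int) -> float:
        return self.t0 + idx / self.sampling_rate


def _window_indices(trace: SignalTrace, start: float, stop: float,
                    closed_end: bool) -> tuple[int, int] | None:
    """Sample index range covering [start, stop] (or [start, stop) when
    ``closed_end`` is False).  None when the window is truncated."""
    fs = trace.sampling_rate
    lo = (start - trace.t0) * fs
    hi = (stop - trace.t0) * fs
    i0 = int(np.ceil(lo - _EPS))
    i1 = int(np.floor(hi + _EPS)) if closed_end else int(np.ceil(hi - _EPS)) - 1
    if i0 < 0 or i1 >= len(trace.values) or i1 < i0:
        return None
    return i0, i1


def baseline(trace: SignalTrace, onset: float,
             statistic: str = "mean") -> float | None:
    """Level over the 1-s pre-onset window [onset-1, onset).

    Returns None (trial invalid) when the window is truncated by the trace
    start rather than raising.
    """
    idx = _window_indices(trace, onset - BASELINE_SPAN, onset,
                          closed_end=False)
    if idx is None:
        return None
    seg = trace.values[idx[0]: idx[1] + 1]
    if statistic == "mean":
        return float(np.mean(seg))
    if statistic == "last":
        return float(seg[-1])
    raise ValueError("baseline statistic must be 'mean' or 'last'")


def _windowed(trace: SignalTrace, onset: float, window: tuple[float, float],
              reduce, statistic: str) -> float | None:
    base = baseline(trace, onset, statistic)
    if base is None:
        return None
    idx = _window_indices(trace, onset + window[0], onset + window[1],
                          closed_end=True)
    if idx is None:
        return None
    seg = trace.values[idx[0]: idx[1] + 1]
    return float(reduce(seg) - base)


def eda_response(trace: SignalTrace, onset: float,
                 statistic: str = "mean") -> float | None:
    """Max in [onset+2, onset+7] minus baseline; ties resolve to the
    earliest sample (irrelevant for the value itself)."""
    return _windowed(trace, onset, EDA_WINDOW, np.max, statistic)


def hr_deceleration(trace: SignalTrace, onset: float,
                    statistic: str = "mean") -> float | None:
    """Min in [onset, onset+3] minus baseline."""
    return _windowed(trace, onset, HR_DEC_WINDOW, np.min, statistic)


def hr_acceleration(trace: SignalTrace, onset: float,
                    statistic: str = "mean") -> float | None:
    """Max in [onset+2, onset+6] minus baseline."""
    return _windowed(trace, onset, HR_ACC_WINDOW, np.max, statistic)


def _is_flatline(trace: SignalTrace, onset: float, span_end: float,
                 eps: float) -> bool:
    idx = _window_indices(trace, onset - BASELINE_SPAN, onset + span_end,
                          closed_end=True)
    if idx is None:
        return False
    seg = trace.values[idx[0]: idx[1] + 1]
    return float(np.ptp(seg)) <= eps


def extract_trials(eda_trace: SignalTrace, hr_trace: SignalTrace,
                   markers: pd.DataFrame | None = None,
                   cfg: ExtractionConfig | None = None) -> pd.DataFrame:
    """Per-trial responses for one participant.

    ``markers`` defaults to the EDA trace's own marker table.  A trial is
    invalid on a channel when any window is truncated or (optionally) when
    the baseline+response span is flat — the signature of an acquisition
    artifact.
    """
    cfg = cfg or ExtractionConfig()
    if markers is None:
        markers = eda_trace.markers
    rows = []
    for rec in markers.itertuples(index=False):
        onset = float(rec.onset)
        b_eda = baseline(eda_trace, onset, cfg.baseline_statistic)
        b_hr = baseline(hr_trace, onset, cfg.baseline_statistic)
        eda = eda_response(eda_trace, onset, cfg.baseline_statistic)
        dec = hr_deceleration(hr_trace, onset, cfg.baseline_statistic)
        acc = hr_acceleration(hr_trace, onset, cfg.baseline_statistic)
        valid_eda = eda is not None
        valid_hr = dec is not None and acc is not None
        if cfg.flatline_check:
            if valid_eda and _is_flatline(eda_trace, onset, EDA_WINDOW[1],
                                          cfg.flatline_eps):
                valid_eda = False
            if valid_hr and _is_flatline(hr_trace, onset, HR_ACC_WINDOW[1],
                                         cfg.flatline_eps):
                valid_hr = False
        rows.append({
            "subject_id": eda_trace.subject_id,
            "trial_index": int(rec.trial_index),
            "baseline_eda": b_eda if b_eda is not None else np.nan,
            "baseline_hr": b_hr if b_hr is not None else np.nan,
            "eda_resp": eda if valid_eda else np.nan,
            "hr_dec": dec if valid_hr else np.nan,
            "hr_acc": acc if valid_hr else np.nan,
            "valid_eda": valid_eda,
            "valid_hr": valid_hr,
        })
    return pd.DataFrame(rows)


def standardize(responses: pd.DataFrame) -> pd.DataFrame:
    """Within-participant z-scores over valid trials, pooling all cells.

    Invalid trials are excluded from the mean/SD and left missing.  A
    participant whose valid responses have zero SD on a channel gets all-z
    missing and a ``degenerate_<channel>`` flag.
    """
    df = responses.copy()
    for raw, z in (("eda_resp", "z_eda"), ("hr_dec", "z_hr_dec"),
                   ("hr_acc", "z_hr_acc")):
        df[z] = np.nan
        flag = f"degenerate_{raw}"
        df[flag] = False
        for sid, grp in df.groupby("subject_id"):
            vals = grp[raw].dropna()
            if len(vals) < 2:
                df.loc[grp.index, flag] = True
                continue
            sd = vals.std(ddof=1)
            if sd == 0.0 or not np.isfinite(sd):
                df.loc[grp.index, flag] = True
                continue
            df.loc[grp.index, z] = (grp[raw] - vals.mean()) / sd
    return df


def exclude_subjects(responses: pd.DataFrame,
                     threshold: float = 0.25) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects per channel when their invalid-trial fraction exceeds
    ``threshold``.  Returns (filtered responses, exclusion report).

    A subject excluded on one channel is retained on the other: exclusion
    sets that channel's raw and z columns to missing.
    """
    report_rows = []
    df = responses.copy()
    for channel, valid_col, cols in (
            ("EDA", "valid_eda", ["eda_resp", "z_eda"]),
            ("HR", "valid_hr", ["hr_dec", "hr_acc", "z_hr_dec", "z_hr_acc"])):
        frac = 1.0 - df.groupby("subject_id")[valid_col].mean()
        for sid, f in frac.items():
            if f > threshold:
                present = [c for c in cols if c in df.columns]
                df.loc[df["subject_id"] == sid, present] = np.nan
                df.loc[df["subject_id"] == sid, valid_col] = False
                report_rows.append({
                    "subject_id": sid, "channel": channel,
                    "invalid_fraction": float(f),
                    "reason": f"invalid-trial fraction {f:.2f} exceeds "
                              f"threshold {threshold:.2f}"})
    report = pd.DataFrame(report_rows,
                          columns=["subject_id", "channel",
                                   "invalid_fraction", "reason"])
    return df, report


def retained_subjects(responses: pd.DataFrame, report: pd.DataFrame,
                      channel: str) -> list:
    """Subject ids retained for a channel's analyses after exclusions."""
    all_ids = list(pd.unique(responses["subject_id"]))
    dropped = set(report.loc[report["channel"] == channel, "subject_id"]) \
        if len(report) else set()
    return [s for s in all_ids if s not in dropped]
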