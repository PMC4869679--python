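"""Plain-text (TSV) persistence for trial logs, traces, and trait tables.

Trace files carry ``# key: value`` metadata header lines (subject_id,
channel, sampling_rate, t0) followed by one sample per row; event markers
live in a companion TSV per subject.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import SignalTrace

TRIAL_LOG_COLUMNS = [
    "subject_id", "block", "trial_index", "cell", "condition", "win_prob",
    "bet_opt1", "bet_opt2", "bet_opt3", "chosen_bet", "response_time",
    "outcome", "points_delta",
]

MARKER_COLUMNS = ["trial_index", "onset", "response", "outcome"]


def write_trial_log(trials: pd.DataFrame, path: str | Path) -> None:
    trials[TRIAL_LOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trace(trace: SignalTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {trace.subject_id}\n")
        fh.write(f"# channel: {trace.channel}\n")
        fh.write(f"# sampling_rate: {trace.sampling_rate}\n")
        fh.write(f"# t0: {trace.t0}\n")
        fh.write("value\n")
        np.savetxt(fh, trace.values, fmt="%.6f")
    if trace.markers is not None:
        trace.markers[MARKER_COLUMNS].to_csv(
            path.with_suffix(".markers.tsv"), sep="\t", index=False)


def read_trace(path: str | Path) -> SignalTrace:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    values = np.loadtxt(path, skiprows=len(meta) + 1)
    markers_path = path.with_suffix(".markers.tsv")
    markers = pd.read_csv(markers_path, sep="\t") \
        if markers_path.exists() else None
    return SignalTrace(subject_id=meta["subject_id"], channel=meta["channel"],
                       sampling_rate=float(meta["sampling_rate"]),
                       t0=float(meta["t0"]), values=values, markers=markers)


def write_study(study, directory: str | Path) -> Path:
    """Write a simulated study: per-subject trial logs and traces, the trait
    table, and the ground-truth tables (kept for recovery validation)."""
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    write_trial_log(study.trials, directory / "trials.tsv")
    write_traits(study.traits, directory / "traits.tsv")
    for sid, (eda, hr) in study.traces.items():
        write_trace(eda, directory / "traces" / f"{sid}_eda.tsv")
        write_trace(hr, directory / "traces" / f"{sid}_hr.tsv")
    truth_dir = directory / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    study.truth.trial_truth.to_csv(truth_dir / "trial_truth.tsv", sep="\t",
                                   index=False)
    for ch, df in study.truth.subject_cell_means.items():
        df.to_csv(truth_dir / f"cell_means_{ch}.tsv", sep="\t")
    return directory


def read_study_inputs(directory: str | Path):
    """Load the analysis inputs (trial log, traces, traits) from disk."""
    directory = Path(directory)
    trials = read_trial_log(directory / "trials.tsv")
    traits = read_traits(directory / "traits.tsv")
    traces = {}
    for eda_path in sorted((directory / "traces").glob("*_eda.tsv")):
        sid = eda_path.name[: -len("_eda.tsv")]
        hr_path = eda_path.with_name(f"{sid}_hr.tsv")
        traces[sid] = (read_trace(eda_path), read_trace(hr_path))
    return trials, traces, traits
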