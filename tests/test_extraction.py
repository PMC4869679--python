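"""Windowed response extraction: constructed oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from betarousal import extraction as ex
from betarousal.config import ExtractionConfig


def flat_trace(value=5.0, fs=10.0, duration=30.0, channel="EDA"):
    n = int(duration * fs) + 1
    return ex.SignalTrace("S1", channel, fs, 0.0, np.full(n, value))


class TestBaseline:
    def test_constant_trace(self):
        assert ex.baseline(flat_trace(3.25), onset=10.0) == 3.25

    def test_linear_ramp_enumerated(self):
        # v(t) = t at 10 Hz; baseline window [9, 10) holds samples
        # 9.0, 9.1, ..., 9.9 -> mean 9.45
        fs = 10.0
        t = np.arange(0, 201) / fs
        trace = ex.SignalTrace("S1", "EDA", fs, 0.0, t)
        expected = np.mean(np.arange(90, 100) / fs)
        assert ex.baseline(trace, onset=10.0) == pytest.approx(expected)
        assert expected == 9.45

    def test_truncated_window_flags_invalid(self):
        trace = flat_trace()
        assert ex.baseline(trace, onset=0.5) is None  # not an exception
        assert ex.eda_response(trace, onset=trace.duration - 3.0) is None

    def test_last_sample_statistic(self):
        fs = 10.0
        trace = ex.SignalTrace("S1", "EDA", fs, 0.0,
                               np.arange(0, 201) / fs)
        assert ex.baseline(trace, 10.0, statistic="last") == \
            pytest.approx(9.9)


def _bump(fs, duration, center, width, height, base=0.0):
    t = np.arange(int(duration * fs) + 1) / fs
    tri = np.clip(1.0 - np.abs(t - center) / width, 0.0, None)
    return ex.SignalTrace("S1", "EDA", fs, 0.0, base + height * tri)


class TestWindowedResponses:
    def test_eda_triangular_bump(self):
        trace = _bump(fs=20.0, duration=40.0, center=14.0, width=1.0,
                      height=0.8, base=2.0)
        assert ex.eda_response(trace, onset=10.0) == pytest.approx(0.8)

    def test_bump_outside_window_gives_zero(self):
        trace = _bump(fs=20.0, duration=40.0, center=18.0, width=0.5,
                      height=0.8, base=2.0)  # peak 8 s post-onset
        assert ex.eda_response(trace, onset=10.0) == pytest.approx(0.0)

    def test_hr_deceleration_constructed_dip(self):
        fs = 10.0
        t = np.arange(0, 401) / fs
        vals = 70.0 - 6.0 * np.clip(1 - np.abs(t - 11.5) / 1.0, 0, None)
        trace = ex.SignalTrace("S1", "HR", fs, 0.0, vals)
        assert ex.hr_deceleration(trace, onset=10.0) == pytest.approx(-6.0)
        assert ex.hr_deceleration(flat_trace(70.0, channel="HR"), 10.0) == 0.0

    def test_hr_acceleration_constructed_rebound(self):
        fs = 10.0
        t = np.arange(0, 401) / fs
        vals = 70.0 + 5.0 * np.clip(1 - np.abs(t - 14.0) / 1.0, 0, None)
        trace = ex.SignalTrace("S1", "HR", fs, 0.0, vals)
        assert ex.hr_acceleration(trace, onset=10.0) == pytest.approx(5.0)
        assert ex.hr_acceleration(flat_trace(70.0, channel="HR"), 10.0) == 0.0

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            ex.SignalTrace("S1", "HR", 2.0, 0.0, np.zeros(100))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(seed=st.integers(0, 10_000),
       fs=st.sampled_from([7.0, 10.0, 32.0, 100.0]),
       onset_frac=st.floats(0.0, 1.0))
def test_windowed_extrema_match_exhaustive_scan(seed, fs, onset_frac):
    """The windowed max/min equal a brute-force scan over every sample
    whose time lies inside the window."""
    rng = np.random.default_rng(seed)
    n = int(20 * fs)
    vals = rng.normal(5.0, 1.0, n)
    trace = ex.SignalTrace("S1", "EDA", fs, 0.0, vals)
    onset = 2.0 + onset_frac * 10.0
    times = np.arange(n) / fs
    base_mask = (times >= onset - 1.0 - 1e-9) & (times < onset - 1e-9)
    base = vals[base_mask].mean()
    for fn, (w0, w1), red in ((ex.eda_response, (2, 7), np.max),
                              (ex.hr_deceleration, (0, 3), np.min),
                              (ex.hr_acceleration, (2, 6), np.max)):
        mask = (times >= onset + w0 - 1e-9) & (times <= onset + w1 + 1e-9)
        expected = red(vals[mask]) - base
        assert fn(trace, onset) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), shift=st.floats(-50, 50),
       scale=st.floats(0.1, 9.0))
def test_shift_invariance_and_scale_covariance(seed, shift, scale):
    rng = np.random.default_rng(seed)
    vals = rng.normal(5.0, 1.0, 300)
    a = ex.SignalTrace("S1", "EDA", 10.0, 0.0, vals)
    b = ex.SignalTrace("S1", "EDA", 10.0, 0.0, vals + shift)
    c = ex.SignalTrace("S1", "EDA", 10.0, 0.0, vals * scale)
    for fn in (ex.eda_response, ex.hr_deceleration, ex.hr_acceleration):
        r = fn(a, 12.0)
        assert fn(b, 12.0) == pytest.approx(r, abs=1e-9)
        assert fn(c, 12.0) == pytest.approx(r * scale, rel=1e-9, abs=1e-12)


class TestStandardize:
    @staticmethod
    def _frame(values, valid=None):
        n = len(values)
        return pd.DataFrame({
            "subject_id": ["S1"] * n, "trial_index": range(n),
            "eda_resp": values, "hr_dec": values, "hr_acc": values,
            "valid_eda": valid if valid is not None else [True] * n,
            "valid_hr": valid if valid is not None else [True] * n,
        })

    def test_symmetric_triple(self):
        df = ex.standardize(self._frame([1.0, 2.0, 3.0]))
        assert df["z_eda"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        df = ex.standardize(self._frame(rng.normal(3, 2, 50).tolist()))
        assert df["z_eda"].mean() == pytest.approx(0.0, abs=1e-12)
        assert df["z_eda"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_subject_flagged(self):
        df = ex.standardize(self._frame([2.0] * 10))
        assert df["degenerate_eda_resp"].all()
        assert df["z_eda"].isna().all()

    def test_invalid_trials_left_missing(self):
        frame = self._frame([1.0, 2.0, 3.0, np.nan],
                            valid=[True, True, True, False])
        df = ex.standardize(frame)
        assert df["z_eda"].isna().tolist() == [False, False, False, True]
        assert df["z_eda"].dropna().mean() == pytest.approx(0.0, abs=1e-12)

    def test_zscore_unchanged_by_trace_scaling(self, rng):
        vals = rng.normal(3, 1, 40)
        z1 = ex.standardize(self._frame(vals.tolist()))["z_eda"]
        z2 = ex.standardize(self._frame((vals * 7.3).tolist()))["z_eda"]
        assert np.allclose(z1, z2)


class TestExclusions:
    @staticmethod
    def _cohort(invalid_hr_frac):
        rows = []
        rng = np.random.default_rng(0)
        for sid, frac in invalid_hr_frac.items():
            bad = rng.random(40) < frac
            for k in range(40):
                rows.append({"subject_id": sid, "trial_index": k,
                             "eda_resp": rng.normal(), "valid_eda": True,
                             "hr_dec": np.nan if bad[k] else rng.normal(),
                             "hr_acc": np.nan if bad[k] else rng.normal(),
                             "valid_hr": not bad[k]})
        return pd.DataFrame(rows)

    def test_threshold_rule_per_channel(self):
        df = self._cohort({"S1": 0.45, "S2": 0.0})
        out, report = ex.exclude_subjects(df, threshold=0.25)
        assert set(report["subject_id"]) == {"S1"}
        assert (report["channel"] == "HR").all()
        s1 = out[out["subject_id"] == "S1"]
        assert s1["hr_dec"].isna().all()       # dropped from HR analyses
        assert s1["eda_resp"].notna().all()    # retained for EDA

    def test_clean_cohort_no_exclusions(self):
        df = self._cohort({"S1": 0.0, "S2": 0.0})
        _, report = ex.exclude_subjects(df, threshold=0.25)
        assert len(report) == 0
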