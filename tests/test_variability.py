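import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erfp.exceptions import (
    AggregationError,
    AlignmentError,
    DegenerateInputError,
    ParameterError,
)
from erfp.variability import (
    ConditionTimeCourse,
    VariabilitySeries,
    aggregate,
    combine_axes,
    sliding_sd,
    within_subject_ci,
)

FS = 1000.0


def naive_sliding_sd(x, n_window, alignment="centered"):
    """Brute-force oracle: recompute the sample SD of every window."""
    left = n_window // 2 if alignment == "centered" else n_window - 1
    out = {}
    for i in range(len(x)):
        start = i - left
        end = start + n_window
        if start < 0 or end > len(x):
            continue
        out[i] = 1000.0 * np.std(x[start:end], ddof=1)
    return out


class TestSlidingSD:
    def test_constant_series_all_zero(self):
        out = sliding_sd(np.full(500, 3.7), FS)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_closed_form_four_samples(self):
        # window {1,2,3,4} N·m: sample SD = sqrt(5/3) ≈ 1.29099 N·m
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = sliding_sd(x, sample_rate=1000.0, window_ms=4.0)
        assert out.values[0] == pytest.approx(1290.9944487, abs=1e-6)

    @pytest.mark.parametrize("alignment", ["centered", "trailing"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_naive_recomputation(self, seed, alignment):
        x = np.random.default_rng(seed).standard_normal(400) * 0.05
        out = sliding_sd(x, FS, window_ms=100.0, alignment=alignment)
        oracle = naive_sliding_sd(x, 100, alignment)
        centers = {int(t) for t in out.times_ms}
        assert centers == set(oracle)
        for t, v in zip(out.times_ms, out.values):
            assert v == pytest.approx(oracle[int(t)], abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_translation_and_scale_equivariance(self, shift, scale, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        base = sliding_sd(x, FS).values
        shifted = sliding_sd(x + shift, FS).values
        scaled = sliding_sd(x * scale, FS).values
        np.testing.assert_allclose(shifted, base, atol=1e-6)
        np.testing.assert_allclose(scaled, np.abs(scale) * base, atol=1e-6)

    def test_short_series_rejected(self):
        with pytest.raises(ParameterError, match="padded"):
            sliding_sd(np.zeros(50), FS, window_ms=100.0)

    def test_non_integer_step_rejected(self):
        with pytest.raises(ParameterError, match="step"):
            sliding_sd(np.zeros(500), FS, step_ms=0.4)


def _vs(values, times=None, axis="ML"):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if times is None else np.asarray(times)
    return VariabilitySeries(times_ms=t, values=values, axis=axis)


class TestCombineAxes:
    def test_pointwise_mean_and_idempotence(self, rng):
        ml = _vs(rng.uniform(0, 10, 50))
        ap = _vs(rng.uniform(0, 10, 50), axis="AP")
        out = combine_axes(ml, ap)
        np.testing.assert_allclose(out.values, (ml.values + ap.values) / 2)
        assert out.axis == "combined"
        same = combine_axes(ml, ml)
        np.testing.assert_allclose(same.values, ml.values)
        # combined lies between ML and AP everywhere
        assert np.all(out.values >= np.minimum(ml.values, ap.values) - 1e-12)
        assert np.all(out.values <= np.maximum(ml.values, ap.values) + 1e-12)

    def test_simple_example(self):
        out = combine_axes(_vs([2.0]), _vs([4.0], axis="AP"))
        assert out.values[0] == 3.0

    def test_mismatched_time_bases_rejected(self):
        with pytest.raises(AlignmentError):
            combine_axes(_vs([1.0, 2.0]), _vs([1.0, 2.0], times=[5.0, 6.0]))


def _trial_table(participants, trials_per, soa_cycle=(100, 1000)):
    import pandas as pd

    rows = []
    for p in participants:
        for i in range(trials_per):
            rows.append(
                {"participant": p, "trial": i + 1, "soa": soa_cycle[i % len(soa_cycle)]}
            )
    return pd.DataFrame(rows)


class TestAggregate:
    def test_identical_trials_and_hand_mean(self, rng):
        trials = _trial_table([1], 3, soa_cycle=(100,))
        vals = [rng.uniform(0, 5, 20) for _ in range(3)]
        series = [(1, i + 1, _vs(v)) for i, v in enumerate(vals)]
        out = aggregate(series, trials, ["soa"])
        assert len(out) == 1
        np.testing.assert_allclose(out[0].series.values, np.mean(vals, axis=0))
        # two identical trials average to themselves
        twice = aggregate(series[:1] * 2, trials.iloc[[0]], ["soa"])
        np.testing.assert_allclose(twice[0].series.values, vals[0])

    def test_two_timecourses_per_participant_for_soa(self, rng):
        trials = _trial_table([1, 2], 4)
        series = [
            (p, i + 1, _vs(rng.uniform(0, 5, 10))) for p in (1, 2) for i in range(4)
        ]
        out = aggregate(series, trials, ["soa"])
        assert len(out) == 4  # 2 participants x 2 SOA levels
        assert {tc.condition for tc in out} == {(100,), (1000,)}

    def test_permutation_invariance(self, rng):
        trials = _trial_table([1], 4)
        series = [(1, i + 1, _vs(rng.uniform(0, 5, 10))) for i in range(4)]
        a = aggregate(series, trials, ["soa"])
        b = aggregate(series[::-1], trials, ["soa"])
        for x, y in zip(a, b):
            assert x.condition == y.condition
            np.testing.assert_allclose(x.series.values, y.series.values)

    def test_empty_cell_names_participant(self, rng):
        trials = _trial_table([1, 2], 2)
        series = [
            (1, 1, _vs(rng.uniform(0, 5, 10))),
            (1, 2, _vs(rng.uniform(0, 5, 10))),
            (2, 1, _vs(rng.uniform(0, 5, 10))),  # participant 2 misses soa=1000
        ]
        with pytest.raises(AggregationError, match="participant 2"):
            aggregate(series, trials, ["soa"])


def _tc(p, cond, values):
    return ConditionTimeCourse(participant=p, condition=cond, series=_vs(values))


class TestWithinSubjectCI:
    def test_identical_participants_zero_width(self):
        tcs = [_tc(p, c, [4.0, 5.0]) for p in (1, 2, 3) for c in (("a",), ("b",))]
        ribbons = within_subject_ci(tcs)
        for hw in ribbons.values():
            np.testing.assert_allclose(hw, 0.0, atol=1e-12)

    def test_matches_hand_computed_centered_se(self):
        # 3 participants x 2 conditions, single time point
        data = {(1, "a"): 10.0, (1, "b"): 12.0, (2, "a"): 20.0, (2, "b"): 26.0,
                (3, "a"): 30.0, (3, "b"): 31.0}
        tcs = [_tc(p, (c,), [v]) for (p, c), v in data.items()]
        ribbons = within_subject_ci(tcs, level=0.95)
        # oracle: center on participant means, Morey-correct the SE
        import scipy.stats as ss

        arr = np.array([[10, 12], [20, 26], [30, 31]], dtype=float)
        centered = arr - arr.mean(axis=1, keepdims=True) + arr.mean()
        se = centered.std(axis=0, ddof=1) / np.sqrt(3) * np.sqrt(2 / 1)
        expected = ss.t.ppf(0.975, 2) * se
        assert ribbons[("a",)][0] == pytest.approx(expected[0], abs=1e-12)
        assert ribbons[("b",)][0] == pytest.approx(expected[1], abs=1e-12)

    def test_level_zero_gives_zero(self):
        tcs = [_tc(p, ("a",), [float(p)]) for p in (1, 2, 3)]
        tcs += [_tc(p, ("b",), [2.0 * p]) for p in (1, 2, 3)]
        ribbons = within_subject_ci(tcs, level=0.0)
        for hw in ribbons.values():
            np.testing.assert_allclose(hw, 0.0, atol=1e-12)

    def test_single_participant_rejected(self):
        with pytest.raises(DegenerateInputError):
            within_subject_ci([_tc(1, ("a",), [1.0])])
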