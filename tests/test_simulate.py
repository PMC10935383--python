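"""Mechanism injectors, device models and cohort generator."""
import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from wearmiss import (
    MechanismSpec,
    SleepModel,
    inject_buffer_loss,
    inject_gap_process,
    inject_iid_dropout,
    inject_overflow_stop,
    inject_time_dependent_dropout,
    simulate_cohort,
    simulate_scan_times,
)
from wearmiss.gaps import extract_gaps


class TestIidDropout:
    def test_zero_rate_all_observed(self):
        assert not inject_iid_dropout(100, 0.0, 1).any()

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            inject_iid_dropout(10, 1.0, 1)

    def test_deterministic_given_seed(self):
        a = inject_iid_dropout(4, 0.5, 123)
        b = inject_iid_dropout(4, 0.5, 123)
        np.testing.assert_array_equal(a, b)

    def test_run_lengths_are_geometric(self):
        # rate 0.2: missing-run lengths ~ geometric(p = 0.8)
        mask = inject_iid_dropout(100_000, 0.2, 42)
        gaps = extract_gaps(mask)
        kmax = 8
        obs = np.bincount(np.minimum(gaps, kmax), minlength=kmax + 1)[1:]
        p = 0.8 * 0.2 ** (np.arange(1, kmax + 1) - 1)
        p[-1] = 0.2 ** (kmax - 1)  # pooled tail
        _, pval = scipy.stats.chisquare(obs, gaps.size * p)
        assert pval > 0.01


class TestGapProcess:
    def test_zero_rate_all_observed(self):
        assert not inject_gap_process(50, 0.0, ("constant", 3), 0).any()

    def test_forced_start_with_constant_size(self):
        mask = inject_gap_process(20, 0.0, ("constant", 3), 0, forced_starts=[5])
        assert np.flatnonzero(mask).tolist() == [5, 6, 7]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            inject_gap_process(50, 0.1, ("weibull", 1.0), 0)

    def test_union_of_overlapping_gaps(self):
        mask = inject_gap_process(20, 0.0, ("constant", 4), 0, forced_starts=[3, 5])
        assert np.flatnonzero(mask).tolist() == [3, 4, 5, 6, 7, 8]

    def test_zipf_sizes_match_sampling_pmf(self):
        rng = np.random.default_rng(77)
        from wearmiss.simulate import sample_gap_sizes

        sizes = sample_gap_sizes(("zipf", 2.0), 10_000, rng)
        kmax = 6
        obs = np.bincount(np.minimum(sizes, kmax), minlength=kmax + 1)[1:]
        p = scipy.stats.zipf.pmf(np.arange(1, kmax + 1), 2.0)
        p[-1] = 1.0 - p[:-1].sum()
        _, pval = scipy.stats.chisquare(obs, sizes.size * p)
        assert pval > 0.01


class TestBufferLoss:
    def test_fifo_hand_trace_with_midpoint_sync(self):
        # 14 h of 15-min samples, 8-h capacity, syncs at 10 h and end:
        # everything before 2 h is lost, the rest survives
        t = np.arange(0, 14.0 + 1e-9, 0.25)
        missing = inject_buffer_loss(t, 8.0, [10.0])
        np.testing.assert_array_equal(missing, t < 2.0)

    def test_fifo_terminal_sync_only(self):
        t = np.arange(0, 14.0 + 1e-9, 0.25)
        missing = inject_buffer_loss(t, 8.0, [])
        np.testing.assert_array_equal(missing, t < 6.0)

    def test_hourly_syncs_lose_nothing(self):
        t = np.arange(0, 14.0, 0.25)
        missing = inject_buffer_loss(t, 8.0, np.arange(1.0, 15.0))
        assert not missing.any()

    def test_empty_timestamps_rejected(self):
        with pytest.raises(ValueError):
            inject_buffer_loss(np.array([]), 8.0, [1.0])

    def test_unsorted_syncs_rejected(self):
        with pytest.raises(ValueError):
            inject_buffer_loss(np.arange(5.0), 8.0, [3.0, 1.0])

    def test_observed_fraction_equals_covered_time(self):
        # conservation: observed fraction = |union of [s - cap, s]| / T
        rng = np.random.default_rng(5)
        T, cap, step = 240.0, 8.0, 0.25
        for _ in range(20):
            syncs = np.sort(rng.choice(np.arange(step, T, step), size=6, replace=False))
            t = np.arange(0.0, T, step)
            missing = inject_buffer_loss(t, cap, syncs)
            intervals = [(max(s - cap, 0.0), s) for s in np.append(syncs, t[-1])]
            merged: list[list[float]] = []
            for lo, hi in sorted(intervals):
                if merged and lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            covered = sum(hi - lo for lo, hi in merged)
            # closed intervals on a step-aligned grid include both endpoints
            n_obs_expected = sum(
                int(round((hi - lo) / step)) + 1 for lo, hi in merged
            )
            assert (~missing).sum() == n_obs_expected
            # continuous covered time agrees up to one grid step per interval
            assert covered / T == pytest.approx(
                (~missing).sum() * step / T, abs=(len(merged) + 1) * step / T
            )

    def test_overflow_stop_records_only_until_full(self):
        t = np.arange(0.0, 14 * 24.0, 1.0)  # hourly over 14 d
        missing = inject_overflow_stop(t, 5 * 24.0, [7 * 24.0])
        # full from day 5 until the day-7 sync clears the memory (a sample at
        # the sync instant itself is recorded), then full again after day 12
        lost = (t > 5 * 24.0) & (t < 7 * 24.0) | (t > 12 * 24.0)
        np.testing.assert_array_equal(missing, lost)


class TestScanTimes:
    def test_zero_rate_gives_empty_stream(self):
        assert simulate_scan_times(SleepModel(), 0.0, 14, 3).size == 0

    def test_poisson_count_on_fixed_wake_schedule(self):
        # awake 16 h/day for 14 days at 0.5 scans/h: expect 112 +- 3*sqrt(112)
        wake = [(24.0 * d + 7.0, 24.0 * d + 23.0) for d in range(14)]
        n = simulate_scan_times(SleepModel(), 0.5, 14, 99, wake_intervals=wake).size
        assert abs(n - 112) <= 3 * np.sqrt(112)

    def test_all_scans_fall_in_waking_intervals(self):
        wake = [(24.0 * d + 7.0, 24.0 * d + 23.0) for d in range(14)]
        for seed in range(5):
            times = simulate_scan_times(SleepModel(), 0.5, 14, seed, wake_intervals=wake)
            ok = np.zeros(times.size, dtype=bool)
            for lo, hi in wake:
                ok |= (times >= lo) & (times < hi)
            assert ok.all()


class TestTimeDependentDropout:
    def test_single_hot_hour(self):
        hours = np.repeat(np.arange(24), 60)
        profile = np.zeros(24)
        profile[23] = 0.5
        mask = inject_time_dependent_dropout(hours, profile, 0)
        assert set(hours[mask]) == {23}

    def test_flat_profile_matches_iid_rate(self):
        hours = np.arange(100_000) % 24
        mask = inject_time_dependent_dropout(hours, np.full(24, 0.1), 7)
        assert mask.mean() == pytest.approx(0.1, abs=0.01)

    def test_wrong_profile_length_rejected(self):
        with pytest.raises(ValueError):
            inject_time_dependent_dropout(np.arange(10), np.zeros(23), 0)


class TestCohortGenerator:
    def test_no_mechanism_means_no_injected_missingness(self):
        cohort = simulate_cohort(1, days=1, seed=0)
        for gt in cohort.truth:
            assert not gt.injected.any()

    def test_same_seed_is_bit_identical(self):
        a = simulate_cohort(3, days=2, seed=5, mechanisms={"hr": MechanismSpec("mcar_iid", rate=0.1)})
        b = simulate_cohort(3, days=2, seed=5, mechanisms={"hr": MechanismSpec("mcar_iid", rate=0.1)})
        for ra, rb in zip(a.raw, b.raw):
            np.testing.assert_array_equal(ra.times, rb.times)
            np.testing.assert_array_equal(ra.values, rb.values)
        for ta, tb in zip(a.truth, b.truth):
            np.testing.assert_array_equal(ta.injected, tb.injected)
        assert a.descriptives.equals(b.descriptives)

    def test_realised_iid_fraction_matches_rate(self):
        cohort = simulate_cohort(
            50, seed=17,
            mechanisms={"glucose": MechanismSpec("mcar_iid", rate=0.10)},
            modalities=("glucose",),
        )
        pooled = np.concatenate([gt.injected for gt in cohort.truth])
        assert pooled.mean() == pytest.approx(0.10, abs=0.01)

    def test_unsupported_kind_rejected(self):
        with pytest.raises(ValueError):
            MechanismSpec("mar_snacks")

    def test_zero_coded_streams_and_descriptive_ranges(self):
        cohort = simulate_cohort(
            20, days=2, seed=9,
            mechanisms={"hr": MechanismSpec("mcar_iid", rate=0.2)},
        )
        hr = [r for r in cohort.raw if r.modality == "hr"]
        truth = {t.subject_id: t for t in cohort.truth if t.modality == "hr"}
        for rs in hr:
            inj = truth[rs.subject_id].injected
            assert (rs.values[inj] == 0).all()  # device zero-codes missing minutes
            assert (rs.values[~inj] > 0).all()
        d = cohort.descriptives
        assert d["age_years"].between(30, 90).all()
        assert d["bmi"].between(18, 50).all()
        assert d["hba1c_mmol_mol"].between(35, 100).all()
        assert set(d["gender"]) <= {"male", "female"}

    def test_step_values_contain_genuine_daytime_zero_runs(self):
        cohort = simulate_cohort(2, days=2, seed=3, modalities=("hr", "steps"))
        steps = [r for r in cohort.raw if r.modality == "steps"]
        for rs in steps:
            assert (rs.values == 0).any() and (rs.values > 0).any()

    @given(st.integers(0, 30))
    def test_mask_union_property(self, seed):
        a = inject_iid_dropout(200, 0.1, seed)
        b = inject_gap_process(200, 0.02, ("constant", 5), seed + 1)
        combined = a | b
        assert combined.sum() >= max(a.sum(), b.sum())
        np.testing.assert_array_equal(combined, b | a)
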