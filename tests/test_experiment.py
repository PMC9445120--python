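"""Monte-Carlo engine: repetitions, condition summaries, schedule grids."""

import numpy as np
import pytest

import patlaksim as ps
from patlaksim.experiment import condition_seed


def make_condition(**overrides):
    base = dict(
        ifn=ps.fixture_library("pertuzumab-like"),
        schedule=ps.SamplingSchedule.from_imaging_times([24, 48, 96]),
        ref=ps.KineticParameters(5e-3, 0.2),
        noise0=0.05,
        n_reps=500,
        seed=42,
    )
    base.update(overrides)
    return ps.Condition(**base)


class TestRunRepetition:
    def test_zero_deviates_give_pure_trapezoid_bias(self):
        cond = make_condition()
        ki0, vt0 = ps.run_repetition(cond, np.zeros(3))
        assert ki0 < cond.ref.ki  # trapezoid AUC overestimation biases Ki low
        # and equals the direct noise-free composition
        plasma = ps.SampledCurve(
            np.asarray(cond.schedule.plasma_times),
            ps.evaluate(cond.ifn, np.asarray(cond.schedule.plasma_times)),
        )
        t = np.asarray(cond.schedule.imaging_times)
        tissue = ps.SampledCurve(t, ps.simulate_tac(cond.ifn, cond.ref, t))
        x, y = ps.patlak_coordinates(plasma, tissue, cond.schedule)
        fit = ps.fit_patlak(x, y)
        assert ki0 == pytest.approx(fit.ki_hat, rel=1e-12)
        assert vt0 == pytest.approx(fit.vt_hat, rel=1e-12)

    def test_noiseless_condition_ignores_deviates(self):
        cond = make_condition(noise0=0.0)
        a = ps.run_repetition(cond, np.zeros(3))
        b = ps.run_repetition(cond, np.array([2.0, -1.0, 0.5]))
        assert a == b

    def test_matches_vectorized_condition_path(self):
        """Single-repetition pipeline and batched OLS agree deviate-for-deviate."""
        cond = make_condition(n_reps=5)
        rng = np.random.default_rng(cond.seed)
        z = rng.standard_normal((cond.n_reps, 3))
        singles = np.array([ps.run_repetition(cond, zi) for zi in z])
        summary = ps.run_condition(cond)
        assert summary.mean_ki == pytest.approx(singles[:, 0].mean(), rel=1e-10)
        assert summary.mean_vt == pytest.approx(singles[:, 1].mean(), rel=1e-10)


class TestRunCondition:
    def test_noise_free_summary_is_deterministic_bias(self):
        cond = make_condition(noise0=0.0, n_reps=10)
        s = ps.run_condition(cond)
        ki0, vt0 = ps.run_repetition(cond, np.zeros(3))
        assert s.sd_ki == 0.0 and s.sd_vt == 0.0
        assert s.variability_ki_pct == 0.0
        assert s.mean_ki == pytest.approx(ki0, rel=1e-12)
        assert s.bias_ki_pct == pytest.approx(
            100 * (ki0 - cond.ref.ki) / cond.ref.ki, rel=1e-9
        )

    def test_same_seed_is_bit_identical(self):
        a = ps.run_condition(make_condition())
        b = ps.run_condition(make_condition())
        assert a == b

    def test_monte_carlo_mean_converges_to_noise_free_estimate(self):
        cond = make_condition(n_reps=2000, seed=7)
        s = ps.run_condition(cond)
        ki0, vt0 = ps.run_repetition(cond, np.zeros(3))
        # estimator is linear in the deviates, so the MC mean is Gaussian
        # around the noise-free estimate; 4 SE keeps the fixed-seed check
        # far out in the tail while still binding
        assert abs(s.mean_ki - ki0) < 4 * s.sd_ki / np.sqrt(cond.n_reps)
        assert abs(s.mean_vt - vt0) < 4 * s.sd_vt / np.sqrt(cond.n_reps)

    def test_variability_scales_linearly_with_noise_level(self):
        lo = ps.run_condition(make_condition(noise0=0.05, n_reps=1000, seed=3))
        hi = ps.run_condition(make_condition(noise0=0.15, n_reps=1000, seed=11))
        assert 2.8 < hi.sd_ki / lo.sd_ki < 3.2
        assert 2.8 < hi.sd_vt / lo.sd_vt < 3.2

    def test_summary_invariant_relations(self):
        s = ps.run_condition(make_condition())
        ref = make_condition().ref
        assert s.bias_ki_pct == pytest.approx(100 * (s.mean_ki - ref.ki) / ref.ki)
        assert s.variability_vt_pct == pytest.approx(100 * s.sd_vt / ref.vt)
        assert s.n_failed == 0

    def test_noise_requires_positive_reversible_volume(self):
        with pytest.raises(ValueError):
            make_condition(ref=ps.KineticParameters(5e-3, 0.0), noise0=0.05)


class TestEnumerateSchedules:
    def test_default_candidate_set_yields_ten_combinations(self):
        assert len(ps.enumerate_schedules()) == 10

    def test_requiring_24h_yields_six(self):
        scheds = ps.enumerate_schedules(require_time=24.0)
        assert len(scheds) == 6
        assert all(24.0 in s.imaging_times for s in scheds)

    def test_full_size_subset_is_unique(self):
        assert len(ps.enumerate_schedules(k=5)) == 1

    def test_k_larger_than_candidates_rejected(self):
        with pytest.raises(ValueError):
            ps.enumerate_schedules([24, 48], 3)

    def test_missing_required_time_gives_empty(self):
        assert ps.enumerate_schedules(require_time=33.0) == []


class TestRunGrid:
    @pytest.fixture
    def small_config(self):
        return ps.ExperimentConfig(
            fixtures=["pertuzumab-like"],
            rki_values=[5e-3],
            rvt_values=[0.2],
            noise_levels=[0.05],
            n_reps=50,
            seed=5,
        )

    def test_row_count_and_schema(self, small_config):
        df = ps.run_grid(small_config)
        assert len(df) == 10  # one fixture, all 10 schedules, one cell
        assert list(df.columns) == [
            "if_label", "t1_h", "t2_h", "t3_h", "rki_per_h", "rvt", "noise_pct",
            "n_reps", "n_failed", "mean_ki", "bias_ki_pct", "variability_ki_pct",
            "mean_vt", "bias_vt_pct", "variability_vt_pct",
        ]
        assert (df["n_failed"] == 0).all()
        assert (df["bias_ki_pct"] < 0).all()

    def test_identical_master_seed_reproduces_table(self, small_config):
        df1 = ps.run_grid(small_config)
        df2 = ps.run_grid(small_config)
        assert df1.equals(df2)

    def test_adding_cells_leaves_existing_cells_untouched(self, small_config):
        df1 = ps.run_grid(small_config)
        bigger = ps.ExperimentConfig(
            fixtures=["pertuzumab-like", "huJ591-like"],
            rki_values=[5e-3], rvt_values=[0.2], noise_levels=[0.05],
            n_reps=50, seed=5,
        )
        df2 = ps.run_grid(bigger)
        sub = df2[df2.if_label == "pertuzumab-like"].reset_index(drop=True)
        assert sub.equals(df1)

    def test_condition_seed_is_stable_and_bounded(self):
        s = condition_seed(123, "pertuzumab-like|24/48/96|0.005|0.2|0.05")
        assert s == condition_seed(123, "pertuzumab-like|24/48/96|0.005|0.2|0.05")
        assert 0 <= s < 2**31
        assert s != condition_seed(124, "pertuzumab-like|24/48/96|0.005|0.2|0.05")
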