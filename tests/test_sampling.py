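"""Parameter distribution fitting, admissibility rules, dataset generation."""

import numpy as np
import pandas as pd
import pytest

from lipoinfer import (
    CurvePool,
    LabeledDataset,
    LogNormalParameterModel,
    Params2D,
    T_ALL,
    admissible,
    build_ranges,
    fit_lognormal,
    generate_dataset,
    integrate,
)
from lipoinfer.sampling import DEFAULT_RULES, _shape_flags, _split_tags


def _frame(cols):
    return pd.DataFrame(cols, index=pd.RangeIndex(1, len(next(iter(cols.values()))) + 1,
                                                  name="subject"))


class TestRanges:
    def test_min_max(self):
        df = _frame({"a": [2.0, 4.0, 6.0]})
        assert build_ranges(df) == {"a": (2.0, 6.0)}

    def test_exclusion_shrinks_range(self):
        df = _frame({"a": [2.0, 4.0, 6.0]})
        assert build_ranges(df, exclude=[3]) == {"a": (2.0, 4.0)}

    def test_matches_direct_recomputation(self, cohort_2d):
        _, truth = cohort_2d
        r = build_ranges(truth)
        for c in truth.columns:
            assert r[c] == (truth[c].min(), truth[c].max())


class TestLogNormalModel:
    def test_log_mean_hand_case(self):
        df = _frame({"a": [1.0, np.e, np.e ** 2]})
        m = LogNormalParameterModel().fit(df)
        assert m.log_mean_[0] == pytest.approx(1.0)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="cannot take logs"):
            LogNormalParameterModel().fit(_frame({"a": [1.0, -2.0, 3.0]}))

    def test_generate_and_refit_recovers_log_mean(self):
        rng = np.random.default_rng(0)
        mu, sd = np.log(5.0), 0.4
        draws = np.exp(rng.normal(mu, sd, 10000))
        m = LogNormalParameterModel().fit(_frame({"a": draws}))
        assert abs(m.log_mean_[0] - mu) < 3 * sd / np.sqrt(10000)

    def test_samples_within_ranges_and_reproducible(self, dist_2d):
        s1 = dist_2d.sample(3000, seed=5)
        s2 = dist_2d.sample(3000, seed=5)
        assert np.array_equal(s1, s2)
        lo = np.array([dist_2d.ranges_[c][0] for c in dist_2d.names_])
        hi = np.array([dist_2d.ranges_[c][1] for c in dist_2d.names_])
        assert np.all(s1 >= lo) and np.all(s1 <= hi)

    def test_median_consistency(self, dist_2d):
        """Marginal medians of samples sit near exp(log_mean) (mild rejection
        bias allowed)."""
        s = dist_2d.sample(20000, seed=6)
        med = np.median(s, axis=0)
        expected = np.exp(dist_2d.log_mean_)
        assert np.all(np.abs(np.log(med) - np.log(expected)) < 0.2)

    def test_correlation_recovery_wide_ranges(self):
        """With ranges wide enough that rejection is rare, the sample log
        correlation matches the fitted correlation within 0.05."""
        rng = np.random.default_rng(1)
        cov = np.array([[0.09, 0.05], [0.05, 0.09]])
        logs = rng.multivariate_normal([0.0, 1.0], cov, size=4000)
        df = _frame({"a": np.exp(logs[:, 0]), "b": np.exp(logs[:, 1])})
        m = LogNormalParameterModel().fit(df)
        s = np.log(m.sample(50000, seed=2))
        corr = np.corrcoef(s, rowvar=False)[0, 1]
        fitted = m.log_cov_[0, 1] / np.sqrt(m.log_cov_[0, 0] * m.log_cov_[1, 1])
        assert abs(corr - fitted) < 0.05

    def test_inconsistent_ranges_raise(self, dist_2d):
        import copy
        m = copy.deepcopy(dist_2d)
        m.log_mean_ = m.log_mean_ + 10  # pushes every draw out of range
        with pytest.raises(RuntimeError, match="acceptance rate"):
            m.sample(100, seed=0)


class TestAdmissibility:
    def _traj(self, F, model_id="2d", G=None):
        from lipoinfer.ode import Trajectory
        if model_id == "2d":
            states = np.column_stack([F, np.zeros_like(F)])
        else:
            states = np.column_stack([G, F, np.zeros_like(F)])
        grid = T_ALL[:len(F)]
        return Trajectory(t=grid, states=states, model_id=model_id)

    def test_negative_ffa_rejected_with_reason(self):
        F = np.linspace(400, -1, 28)
        ok, reason = admissible(self._traj(F))
        assert not ok and reason == "negative_F"

    def test_single_dip_accepted(self):
        t = np.arange(28.0)
        F = 400 - 300 * np.exp(-((t - 14) / 6) ** 2)
        ok, reason = admissible(self._traj(F))
        assert ok and reason == "ok"

    def test_double_dip_rejected(self):
        t = np.arange(28.0)
        F = 400 - 200 * np.exp(-((t - 8) / 3) ** 2) \
            - 250 * np.exp(-((t - 20) / 3) ** 2)
        ok, reason = admissible(self._traj(F))
        assert not ok and reason == "shape_F"

    def test_rising_glucose_rejected(self):
        F = np.linspace(500, 400, 16)
        G = np.linspace(150, 250, 16)  # rises far above basal
        ok, reason = admissible(self._traj(F, "3d", G), Gb=90.0)
        assert not ok and reason == "shape_G"

    def test_filter_matches_rule_oracle(self, dist_2d, pools_2d):
        """Vectorized filter decisions equal an independent loop-based
        re-implementation of the rules on random parameter sets."""
        pool, gpool = pools_2d
        ds = generate_dataset(dist_2d, pool, 1000, "2d", seed=3,
                              glucose_pool=gpool, apply_filter=False)
        flags = _shape_flags(ds.traj, None, "2d", DEFAULT_RULES)

        def oracle(F):
            if np.any(F < 0) or not np.all(np.isfinite(F)):
                return False
            k = int(np.argmin(F))
            tol = DEFAULT_RULES["f_tol"]
            for i in range(len(F) - 1):
                if i < k and F[i + 1] > F[i] * (1 + tol) + 1e-300:
                    return False
                if i >= k and F[i + 1] < F[i] * (1 - tol) - 1e-300:
                    return False
            return True

        got = flags == 0
        exp = np.array([oracle(ds.traj[i, :, 0]) for i in range(len(ds))])
        assert np.array_equal(got, exp)


class TestGenerateDataset:
    def test_empty_target(self, dist_2d, pools_2d):
        pool, gpool = pools_2d
        ds = generate_dataset(dist_2d, pool, 0, "2d", seed=0,
                              glucose_pool=gpool)
        assert len(ds) == 0

    def test_insulin_ids_unique(self, small_dataset_2d):
        assert len(np.unique(small_dataset_2d.insulin_id)) == len(small_dataset_2d)

    def test_filters_disabled_accepts_everything(self, dist_2d, pools_2d):
        pool, gpool = pools_2d
        ds = generate_dataset(dist_2d, pool, 500, "2d", seed=1,
                              glucose_pool=gpool, apply_filter=False)
        assert ds.acceptance_rate == 1.0

    def test_pool_exhaustion_raises(self, dist_2d, gp_pools_2d):
        gp_i, gp_g = gp_pools_2d
        pool = CurvePool(gp_i.sample(50, seed=1))
        gpool = CurvePool(gp_g.sample(50, seed=2))
        with pytest.raises(RuntimeError, match="pool exhausted"):
            generate_dataset(dist_2d, pool, 5000, "2d", seed=2,
                             glucose_pool=gpool)

    def test_rows_reintegrate_to_stored_trajectory(self, small_dataset_2d):
        """Self-consistency: stored rows re-integrate (adaptively, from their
        stored parameters and input curves) to the stored concentrations."""
        ds = small_dataset_2d
        for i in range(0, len(ds), 200):
            from lipoinfer import InputSignal
            p = Params2D(**dict(zip(ds.param_names, ds.params[i])))
            tr = integrate("2d", p,
                           {"insulin": InputSignal(T_ALL, ds.insulin[i]),
                            "glucose": InputSignal(T_ALL, ds.glucose[i])})
            rel = np.abs(tr.F - ds.traj[i, :, 0]) / np.abs(ds.traj[i, :, 0])
            assert rel.max() < 1e-6

    def test_accepted_medians_inside_fitted_ranges(self, small_dataset_2d, dist_2d):
        med = np.median(small_dataset_2d.params, axis=0)
        for j, c in enumerate(small_dataset_2d.param_names):
            lo, hi = dist_2d.ranges_[c]
            assert lo <= med[j] <= hi

    def test_split_tags_deterministic_and_sized(self):
        a = _split_tags(5000, seed=4)
        b = _split_tags(5000, seed=4)
        assert np.array_equal(a, b)
        frac = (a == "train").mean()
        assert 0.88 < frac < 0.92

    def test_h5_round_trip(self, small_dataset_2d, tmp_path):
        path = tmp_path / "ds.h5"
        small_dataset_2d.save(path)
        back = LabeledDataset.load(path)
        assert np.array_equal(back.params, small_dataset_2d.params)
        assert np.array_equal(back.traj, small_dataset_2d.traj)
        assert back.param_names == small_dataset_2d.param_names
        assert np.array_equal(back.split, small_dataset_2d.split)
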