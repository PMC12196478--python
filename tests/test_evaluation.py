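"""Fold-error metrics, error percentages, R² and acceptance verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aztreonam_pbpk.evaluation import (
    aafe,
    afe,
    are,
    build_report,
    flag_outliers,
    fold_error,
    r_squared,
    rpe,
)
from aztreonam_pbpk.parameters import ParameterError


class TestFoldError:
    @pytest.mark.parametrize("pred,obs,fe", [(1, 1, 1.0), (2, 1, 2.0), (0.3, 1, 0.3)])
    def test_ratio(self, pred, obs, fe):
        assert fold_error(pred, obs) == pytest.approx(fe)

    def test_boundary_value_is_inside_acceptance(self):
        report = build_report(observed=[1.0, 1.0], predicted=[0.3, 3.0])
        assert report.fe_within_bounds  # 0.3 and 3 inclusive

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            fold_error(0.0, 1.0)


class TestAverageFoldErrors:
    def test_opposite_twofold_errors(self):
        pairs = [(2.0, 1.0), (0.5, 1.0)]
        assert afe(pairs) == pytest.approx(1.0)
        assert aafe(pairs) == pytest.approx(2.0)

    def test_perfect_predictions(self):
        pairs = [(3.0, 3.0), (0.2, 0.2)]
        assert afe(pairs) == pytest.approx(1.0)
        assert aafe(pairs) == pytest.approx(1.0)

    def test_constant_threefold_overprediction(self):
        pairs = [(3.0, 1.0), (6.0, 2.0), (30.0, 10.0)]
        assert afe(pairs) == pytest.approx(3.0)
        assert aafe(pairs) == pytest.approx(3.0)

    @given(
        st.lists(
            st.tuples(st.floats(0.01, 100), st.floats(0.01, 100)),
            min_size=1,
            max_size=12,
        )
    )
    def test_inversion_antisymmetry(self, pairs):
        inverted = [(o, p) for p, o in pairs]
        assert afe(pairs) * afe(inverted) == pytest.approx(1.0, rel=1e-9)
        assert aafe(pairs) == pytest.approx(aafe(inverted), rel=1e-9)
        assert aafe(pairs) >= max(afe(pairs), 1 / afe(pairs)) - 1e-12
        assert aafe(pairs) >= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            afe([])


class TestRelativeErrors:
    def test_mouse_auc_worked_example(self):
        assert round(rpe(30.05, 31.26), 1) == 4.0

    def test_dog_auc_worked_example(self):
        assert round(rpe(37.10, 42.96), 1) == 15.8

    def test_exact_prediction_is_zero(self):
        assert rpe(5.0, 5.0) == 0.0

    def test_are_is_absolute_rpe(self):
        for o, p in [(30.05, 31.26), (0.017, 0.016), (6.48, 4.66)]:
            assert are(o, p) == abs(rpe(o, p))

    def test_zero_observed_rejected(self):
        with pytest.raises(ParameterError):
            rpe(0.0, 1.0)


class TestRSquared:
    def test_identical_series(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_proportionality(self):
        assert r_squared([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_anticorrelated_but_linear_toy_set(self):
        # OLS of predicted on observed: exact fit pred = 4 - obs
        assert r_squared([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_matches_squared_correlation_oracle(self):
        rng = np.random.default_rng(11)
        obs = rng.uniform(1, 10, 25)
        pred = 2 * obs + rng.normal(0, 1, 25)
        oracle = float(np.corrcoef(obs, pred)[0, 1] ** 2)
        assert r_squared(obs, pred) == pytest.approx(oracle, rel=1e-10)

    def test_identity_variant_penalises_bias(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, 2 * obs, against_identity=True) < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestOutliers:
    def test_high_fold_error_flagged(self):
        pts = pd.DataFrame({"fe": [12.37, 2.9, 0.5]})
        out, log = flag_outliers(pts)
        assert list(out["outlier"]) == [True, False, False]
        assert len(log) == 1
        assert len(out) == 3  # retained unless exclusion enabled

    def test_exclusion_logged(self):
        pts = pd.DataFrame({"fe": [12.37, 2.9]})
        out, log = flag_outliers(pts, exclude=True)
        assert len(out) == 1
        assert log["fe"].iloc[0] == 12.37

    def test_low_side_symmetry(self):
        pts = pd.DataFrame({"fe": [0.2, 0.34]})
        out, _ = flag_outliers(pts)
        assert list(out["outlier"]) == [True, False]

    def test_empty_table(self):
        out, log = flag_outliers(pd.DataFrame({"fe": []}))
        assert out.empty and log.empty


class TestVerdicts:
    def test_acceptable_fit(self):
        obs = [10.0, 5.0, 2.0, 1.0]
        pred = [11.0, 4.5, 2.2, 0.9]
        rep = build_report(observed=obs, predicted=pred)
        assert rep.concentrations_acceptable
        assert rep.afe < 2 and rep.aafe < 2 and rep.r_squared >= 0.8

    def test_single_fe_outside_band_fails(self):
        rep = build_report(observed=[1, 1, 1, 1], predicted=[1, 1, 1, 3.5])
        assert not rep.fe_within_bounds
        assert not rep.concentrations_acceptable

    def test_systematic_bias_fails_afe(self):
        rep = build_report(observed=[1, 2, 4], predicted=[2.5, 5, 10])
        assert rep.afe >= 2
        assert not rep.concentrations_acceptable

    def test_parameter_reliability_threshold(self):
        pars = pd.DataFrame(
            {
                "parameter": ["auc", "cl", "vss"],
                "observed": [100.0, 1.0, 10.0],
                "predicted": [120.0, 1.29, 12.0],
            }
        )
        rep = build_report(parameter_pairs=pars)
        assert rep.parameters_reliable  # all ARE < 30
        pars.loc[1, "predicted"] = 1.31  # 31% error
        rep = build_report(parameter_pairs=pars)
        assert not rep.parameters_reliable

    def test_are_equals_absolute_rpe_rowwise(self):
        pars = pd.DataFrame(
            {
                "parameter": ["a", "b"],
                "observed": [10.0, 4.0],
                "predicted": [8.0, 5.0],
            }
        )
        rep = build_report(parameter_pairs=pars)
        assert (rep.parameters["are_pct"] == rep.parameters["rpe_pct"].abs()).all()
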