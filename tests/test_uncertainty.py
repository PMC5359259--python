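"""Sensitivities, identifiability orthogonalization, and CI bounds."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist

from matefit import (
    FitResult,
    ci_fim,
    ci_regression,
    doubling_time,
    finite_diff_sensitivities,
    identifiability_ranking,
    overall_sensitivity,
    uncertainty_report,
)
from matefit.calibration import predict_observations, weighted_sse
from matefit.uncertainty import IDENTIFIABILITY_CUTOFF

from .conftest import TABLE2_TRUTH


def _frame(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"p{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


# -- independent linear-algebra oracles --------------------------------------

def greedy_orthogonalization_oracle(A):
    """Step-by-step reference: at each step solve the least-squares
    projection of the whole matrix onto the selected original columns
    explicitly and take residual column norms."""
    A = np.asarray(A, dtype=float)
    remaining = list(range(A.shape[1]))
    selected, scores = [], {}
    while remaining:
        if selected:
            X = A[:, selected]
            proj = X @ np.linalg.lstsq(X, A, rcond=None)[0]
            residual = A - proj
        else:
            residual = A
        norms = [np.linalg.norm(residual[:, j]) for j in remaining]
        best = remaining[int(np.argmax(norms))]
        scores[best] = max(norms)
        selected.append(best)
        remaining.remove(best)
    return selected, scores


def regression_ci_oracle(A, sse, m, n, p):
    inv = np.linalg.inv(A.T @ A)
    f = f_dist.ppf(0.95, m, n - m)
    return 100.0 * np.sqrt(m / (n - m) * sse * f * np.diag(inv)) / np.abs(p)


def fim_ci_oracle(A, sigma, p):
    W = np.diag(1.0 / np.asarray(sigma) ** 2)
    inv = np.linalg.inv(A.T @ W @ A)
    return 100.0 * 1.96 * np.sqrt(np.diag(inv)) / np.abs(p)


class TestOverallSensitivity:
    def test_single_row_scores_are_magnitudes(self):
        s = overall_sensitivity(_frame([[3.0, 4.0]]))
        assert s.tolist() == [3.0, 4.0]

    def test_identical_rows_scale_by_sqrt2(self):
        s = overall_sensitivity(_frame([[2.0], [2.0]]))
        assert s.iloc[0] == pytest.approx(2.0 * math.sqrt(2.0))

    def test_zero_column_scores_zero(self):
        s = overall_sensitivity(_frame([[0.0, 1.0], [0.0, 2.0]]))
        assert s.iloc[0] == 0.0


class TestIdentifiabilityRanking:
    def test_orthogonal_columns_rank_by_norm(self):
        A = np.zeros((4, 3))
        A[0, 0], A[1, 1], A[2, 2] = 5.0, 3.0, 7.0
        scores = identifiability_ranking(_frame(A))
        assert [s[0] for s in scores] == ["p2", "p0", "p1"]
        assert [s[1] for s in scores] == pytest.approx([7.0, 5.0, 3.0])

    def test_duplicated_column_scores_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=6)
        A = np.c_[col, 2 * col, rng.normal(size=6)]
        scores = dict(identifiability_ranking(_frame(A)))
        assert min(scores.values()) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_explicit_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(12, 4))
        frame = _frame(A)
        scores = identifiability_ranking(frame)
        order, oracle = greedy_orthogonalization_oracle(A)
        assert [s[0] for s in scores] == [f"p{j}" for j in order]
        for name, value in scores:
            assert value == pytest.approx(oracle[int(name[1:])], abs=1e-10)

    def test_more_columns_than_rows_rejected(self):
        with pytest.raises(ValueError):
            identifiability_ranking(_frame(np.ones((2, 3))))


class TestCiRegression:
    def test_scalar_closed_form(self):
        n = 20
        A = np.ones((n, 1))
        radii = ci_regression(_frame(A), sse=4.0, m=1, n=n,
                              p_hat={"p0": 2.0})
        expected = math.sqrt(1 / (n - 1) * 4.0
                             * f_dist.ppf(0.95, 1, n - 1) / n)
        assert radii.iloc[0] == pytest.approx(100 * expected / 2.0)

    def test_doubling_sensitivities_halves_radius(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(9, 2))
        p = {"p0": 1.0, "p1": 2.0}
        r1 = ci_regression(_frame(A), sse=10.0, m=2, n=9, p_hat=p)
        r2 = ci_regression(_frame(2 * A), sse=10.0, m=2, n=9, p_hat=p)
        np.testing.assert_allclose(r2, r1 / 2.0, rtol=1e-10)

    def test_matches_explicit_inversion_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 2))
        p = np.array([0.7, 1.3])
        radii = ci_regression(_frame(A), sse=3.0, m=2, n=6,
                              p_hat={"p0": 0.7, "p1": 1.3})
        np.testing.assert_allclose(radii,
                                   regression_ci_oracle(A, 3.0, 2, 6, p),
                                   rtol=1e-10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(10, 3))
        p = {f"p{j}": 1.0 for j in range(3)}
        a = ci_regression(_frame(A), sse=5.0, m=3, n=10, p_hat=p)
        b = ci_regression(_frame(A[::-1]), sse=5.0, m=3, n=10, p_hat=p)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestCiFim:
    def test_scalar_fim(self):
        radii = ci_fim(_frame([[4.0]]), sigma=[2.0], p_hat={"p0": 1.0})
        assert radii.iloc[0] == pytest.approx(100 * 1.96 * 2.0 / 4.0)

    def test_diagonal_fim(self):
        A = np.diag([2.0, 5.0])
        radii = ci_fim(_frame(A), sigma=[1.0, 1.0],
                       p_hat={"p0": 1.0, "p1": 1.0})
        np.testing.assert_allclose(radii, [100 * 1.96 / 2, 100 * 1.96 / 5],
                                   rtol=1e-12)

    def test_matches_explicit_inversion_oracle(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(10, 3))
        sigma = rng.uniform(0.5, 2.0, size=10)
        p = np.array([0.5, 1.5, 2.5])
        radii = ci_fim(_frame(A), sigma,
                       p_hat={f"p{j}": p[j] for j in range(3)})
        np.testing.assert_allclose(radii, fim_ci_oracle(A, sigma, p),
                                   rtol=1e-10)

    def test_as_printed_form_switch(self):
        A = np.diag([2.0])
        std = ci_fim(_frame(A), sigma=[1.0], p_hat={"p0": 1.0})
        alt = ci_fim(_frame(A), sigma=[1.0], p_hat={"p0": 1.0},
                     form="as_printed")
        assert std.iloc[0] == pytest.approx(100 * 1.96 * 0.5)
        assert alt.iloc[0] == pytest.approx(100 * math.sqrt(1.96 * 0.25))

    def test_singular_fim_reports_infinite_radii(self):
        col = np.arange(1.0, 5.0)
        A = np.c_[col, 2 * col]
        with pytest.warns(UserWarning, match="singular"):
            radii = ci_fim(_frame(A), sigma=np.ones(4),
                           p_hat={"p0": 1.0, "p1": 1.0})
        assert np.all(np.isinf(radii))


class TestDoublingTime:
    @pytest.mark.parametrize("psi, minutes", [
        (0.0392, 18), (0.0571, 12),
    ])
    def test_published_doubling_times_after_rounding(self, psi, minutes):
        assert round(doubling_time(psi)) == minutes

    def test_unit_rate(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)


def _truth_fit(v15, training_designs, obs):
    ics = {d.id: {"D0": d.schedule.donor_density,
                  "R0": d.schedule.recipient_density}
           for d in training_designs}
    params = v15.resolve(TABLE2_TRUTH)
    sim = predict_observations(params, ics,
                               {d.id: d for d in training_designs})
    return FitResult(variant="V15", free_names=v15.free_names,
                     free_vector=TABLE2_TRUTH, parameters=params,
                     initial_conditions=ics, sse=weighted_sse(sim, obs),
                     m=14, n_obs=obs.n_observations())


class TestModelSensitivities:
    def test_exponential_growth_relative_sensitivity_is_psi_t(
            self, v14, training_designs):
        """For y = D0 exp(psi t), the relative sensitivity to psi is psi*t;
        checked through the full finite-difference machinery with the
        transfer rate at zero."""
        from matefit import NoiseModel, generate_dataset
        truth = [0.02, 0.0]
        designs = training_designs[:1]
        ds = generate_dataset(truth, v14, designs,
                              NoiseModel(cv={"D": 0, "R": 0, "T": 0}),
                              seed=0)
        fit = FitResult(
            variant="V14", free_names=v14.free_names,
            free_vector=np.array(truth), parameters=v14.resolve(truth),
            initial_conditions={designs[0].id: {
                "D0": designs[0].schedule.donor_density,
                "R0": designs[0].schedule.recipient_density}},
            sse=0.0, m=10, n_obs=ds.observations.n_observations())
        with pytest.warns(UserWarning, match="fitted at 0"):
            S = finite_diff_sensitivities(fit, v14, designs)
        rel = S.relative["psi_max"]
        for (exp, sub, t), value in rel.items():
            if sub in ("D", "R"):
                assert value == pytest.approx(0.02 * t, rel=1e-3)

    def test_identifiability_properties_on_synthetic_selected_model(
            self, v15, training_designs, v15_noise_free_data):
        """Scores never exceed overall sensitivity; the top-ranked
        parameter's score equals its sensitivity; the lag half-time is the
        least identifiable parameter; and all parameters clear the 0.04
        identifiability cut-off."""
        obs = v15_noise_free_data.observations
        fit = _truth_fit(v15, training_designs, obs)
        S = finite_diff_sensitivities(fit, v15, training_designs)
        sens = overall_sensitivity(S)
        scores = identifiability_ranking(S)
        for name, score in scores:
            assert score <= sens[name] + 1e-9
        first_name, first_score = scores[0]
        assert first_score == pytest.approx(sens[first_name], rel=1e-12)
        assert scores[-1][0] == "K_L"
        assert all(score > IDENTIFIABILITY_CUTOFF for _, score in scores)

    def test_report_table_shape_and_consistency(self, v15, training_designs):
        from matefit import NoiseModel, generate_dataset
        obs = generate_dataset(TABLE2_TRUTH, v15, training_designs,
                               NoiseModel(), seed=7).observations
        fit = _truth_fit(v15, training_designs, obs)
        report = uncertainty_report(fit, v15, obs, training_designs)
        assert list(report["parameter"]) == list(v15.free_names)
        assert (report["identifiability"]
                <= report["sensitivity"] + 1e-9).all()
        assert sorted(report["identifiability_rank"]) == list(range(1, 7))
        assert (report["ci_fim_pct"] > 0).all()
        assert (report["ci_regression_pct"] > 0).all()
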