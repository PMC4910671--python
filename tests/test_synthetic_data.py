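"""Generator: population moments, sampling, Likert categorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import validitysim as vs
from validitysim.synthetic_data import (
    COLUMNS,
    DataMatrix,
    DegenerateSampleError,
    GeneratingParams,
)


class TestGeneratingParams:
    def test_defaults_satisfy_unit_variance_invariants(self, params):
        assert params.lambda_loading == 0.8
        assert np.allclose(params.error_var, 1 - 0.8**2)
        for j in range(4):
            assert params.gamma[j] ** 2 + params.tau[j] ** 2 + params.zeta_var[
                j
            ] == pytest.approx(1.0)
        assert params.tau[0] == params.tau[1] == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="threat"):
            GeneratingParams(tau=(0.1, 0.0, 0.25, 0.25)).validate()
        with pytest.raises(ValueError, match="state 1 variance"):
            GeneratingParams(zeta_var=(0.5, 0.84, 0.68, 0.68)).validate()

    def test_yaml_round_trip(self, params):
        again = GeneratingParams.from_yaml(params.to_yaml())
        assert again == params


class TestPopulationSigma:
    def test_block_structure(self, params, pop_sigma):
        lam2 = params.lambda_loading**2
        # same state
        assert pop_sigma[0, 1] == pytest.approx(lam2)
        # states 1-2: only the trait connects them
        assert pop_sigma[0, 3] == pytest.approx(
            lam2 * params.gamma[0] * params.gamma[1]
        )
        # states 3-4: trait plus threat
        assert pop_sigma[6, 9] == pytest.approx(
            lam2 * (params.gamma[2] * params.gamma[3] + params.tau[2] * params.tau[3])
        )
        assert np.allclose(np.diag(pop_sigma), 1.0)
        assert np.allclose(pop_sigma, pop_sigma.T)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        lam=st.floats(0.3, 0.95),
        g=st.floats(0.05, 0.6),
        t=st.floats(0.05, 0.6),
    )
    def test_positive_definite_over_admissible_params(self, lam, g, t):
        # rescale so each state keeps positive disturbance variance
        scale = max(1.0, np.hypot(g, t) / 0.95)
        g, t = g / scale, t / scale
        p = GeneratingParams(
            lambda_loading=lam, gamma=(g,) * 4, tau=(0.0, 0.0, t, t)
        )
        sigma = vs.population_sigma(p)
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestSimulateSample:
    def test_reproducible_and_shaped(self, params):
        a = vs.simulate_sample(params, 50, seed=123)
        b = vs.simulate_sample(params, 50, seed=123)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert list(a.values.columns) == list(COLUMNS)
        assert a.is_continuous

    def test_empty_sample_rejected(self, params):
        with pytest.raises(ValueError):
            vs.simulate_sample(params, 0, seed=1)

    def test_large_sample_matches_population_moments(self, params, pop_sigma):
        n = 100_000
        data = vs.simulate_sample(params, n, seed=99)
        x = data.values.to_numpy()
        se_var = np.sqrt(2.0 / n)  # SE of a unit-variance estimate
        assert np.all(np.abs(x.var(axis=0) - 1.0) < 3 * se_var)
        r = np.corrcoef(x, rowvar=False)
        se_r = (1 - pop_sigma[0, 1] ** 2) / np.sqrt(n)
        assert abs(r[0, 1] - pop_sigma[0, 1]) < 3 * se_r

    def test_mean_correlation_converges_to_population(self, params, pop_sigma):
        # average sample correlations over many seeds against the closed form
        n, n_seeds = 400, 200
        entries = np.array(
            [
                np.corrcoef(
                    vs.simulate_sample(params, n, seed=s).values.to_numpy(),
                    rowvar=False,
                )
                for s in range(n_seeds)
            ]
        )
        mean_r = entries.mean(axis=0)
        se = entries.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        off = ~np.eye(12, dtype=bool)
        assert np.all(np.abs(mean_r - pop_sigma)[off] < 3.5 * se[off])


class TestLikertThresholds:
    @pytest.mark.parametrize(
        "k, expected",
        [
            (3, (-1.0, 1.0)),
            (5, (-1.8, -0.6, 0.6, 1.8)),
            (7, tuple(-3 + 6 * i / 7 for i in range(1, 7))),
        ],
    )
    def test_equal_width_cutpoints(self, k, expected):
        thr = vs.likert_thresholds(k)
        assert thr.cutpoints == pytest.approx(expected)
        assert thr.n_categories == k
        # symmetric and strictly inside (-3, 3)
        assert thr.cutpoints == pytest.approx(
            tuple(-c for c in reversed(thr.cutpoints))
        )
        assert -3 < thr.cutpoints[0] and thr.cutpoints[-1] < 3

    def test_unsupported_k(self):
        with pytest.raises(ValueError, match="unsupported"):
            vs.likert_thresholds(4)


class TestDiscretize:
    @pytest.mark.parametrize(
        "value, k, code",
        [(-3.5, 3, 1), (0.0, 3, 2), (1.81, 5, 5), (-1.0, 3, 1), (2.99, 7, 7)],
    )
    def test_single_values(self, value, k, code):
        df = pd.DataFrame(np.full((3, 12), value), columns=COLUMNS)
        out = vs.discretize(DataMatrix(df), k)
        assert out.values.iloc[0, 0] == code
        assert out.scale_kind == f"categorical-{k}"

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_order_preserving_and_rank_idempotent(self, params, k):
        data = vs.simulate_sample(params, 2000, seed=5)
        codes = vs.discretize(data, k).values.to_numpy()
        x = data.values.to_numpy()
        for col in range(12):
            order = np.argsort(x[:, col], kind="stable")
            assert np.all(np.diff(codes[order, col]) >= 0)
        # re-coding the interval midpoints of each code reproduces the codes:
        # the categorization is idempotent on the ranks it induces
        cut = np.array(vs.likert_thresholds(k).cutpoints)
        edges = np.concatenate([[-3.0], cut, [3.0]])
        mids = (edges[:-1] + edges[1:]) / 2
        again = np.searchsorted(cut, mids[codes - 1], side="left") + 1
        assert np.array_equal(again, codes)

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_extreme_categories_populated(self, params, k):
        data = vs.simulate_sample(params, 20_000, seed=11)
        codes = vs.discretize(data, k).values.to_numpy()
        assert np.all(codes.min(axis=0) == 1)
        assert np.all(codes.max(axis=0) == k)

    def test_discretize_requires_continuous(self, params):
        once = vs.discretize(vs.simulate_sample(params, 100, seed=1), 3)
        with pytest.raises(ValueError, match="continuous"):
            vs.discretize(once, 3)


class TestPearsonMatrix:
    def test_duplicate_columns_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(50)
        df = pd.DataFrame({"Y1": col, "Y2": col, "Y3": rng.standard_normal(50)})
        r = vs.pearson_matrix(DataMatrix(df))
        assert r[0, 1] == pytest.approx(1.0)

    def test_zero_variance_column_raises(self):
        df = pd.DataFrame(np.ones((20, 12)), columns=COLUMNS)
        with pytest.raises(DegenerateSampleError):
            vs.pearson_matrix(DataMatrix(df))

    def test_categorization_attenuates_correlation(self, params, pop_sigma):
        data = vs.simulate_sample(params, 100_000, seed=21)
        r_cont = vs.pearson_matrix(data)
        r_cat = vs.pearson_matrix(vs.discretize(data, 3))
        assert abs(r_cont[0, 1] - pop_sigma[0, 1]) < 0.01
        assert r_cat[0, 1] < r_cont[0, 1]


def test_csv_round_trip(params, tmp_path):
    data = vs.simulate_sample(params, 25, seed=8)
    path = tmp_path / "sample.csv"
    data.to_csv(path)
    again = DataMatrix.from_csv(str(path))
    pd.testing.assert_frame_equal(again.values, data.values)
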