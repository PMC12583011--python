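"""Estimation engine: fit indices, ML EFA, rotation, factor-count rules, CFA."""

import numpy as np
import pytest
from sklearn.decomposition import FactorAnalysis

from conftest import clean_two_factor, population_corr
from rfas import facengine
from rfas.synthgen import Dataset, build_loading_matrix, simulate_dataset, study_model_spec

TETRAD_LOADINGS = np.array([0.8, 0.7, 0.6])
#: one-factor correlations implied by loadings (0.8, 0.7, 0.6)
TETRAD_CORR = np.array(
    [[1.0, 0.56, 0.48], [0.56, 1.0, 0.42], [0.48, 0.42, 1.0]]
)


class TestFitIndices:
    def test_hand_computed_example(self):
        fit = facengine.fit_indices(
            chi2=100.0,
            df=30,
            chi2_baseline=1000.0,
            df_baseline=45,
            n=301,
            residual_corr=np.zeros((3, 3)),
        )
        assert fit.cfi == pytest.approx(1.0 - 70.0 / 955.0, abs=1e-6)  # 0.9267
        base = 1000.0 / 45.0
        assert fit.tli == pytest.approx((base - 100.0 / 30.0) / (base - 1.0), abs=1e-6)
        assert fit.rmsea == pytest.approx(np.sqrt(70.0 / (30 * 300)), abs=1e-6)  # 0.0882
        assert fit.srmr == 0.0

    def test_saturated_model_is_perfect(self):
        fit = facengine.fit_indices(0.0, 0, 500.0, 10, 200, np.zeros((4, 4)))
        assert fit.cfi == 1.0 and fit.tli == 1.0 and fit.rmsea == 0.0

    def test_srmr_from_residuals(self):
        res = np.array([[0.0, 0.1], [0.1, 0.0]])
        fit = facengine.fit_indices(5.0, 2, 100.0, 6, 100, res)
        # lower triangle incl. diagonal: (0, 0.1, 0) → √(0.01/3)
        assert fit.srmr == pytest.approx(np.sqrt(0.01 / 3.0), abs=1e-12)

    def test_thresholds(self):
        fit = facengine.fit_indices(10.0, 8, 400.0, 20, 300, np.zeros((5, 5)))
        assert fit.passes(0.9, 0.9, 0.08, 0.08)
        assert not fit.passes(1.0, 0.9, 0.08, 0.08)


class TestMLEFA:
    def test_tetrad_oracle_exact_recovery(self):
        sol = facengine.ml_efa(TETRAD_CORR, 1, n=500)
        assert np.allclose(np.abs(sol.loadings[:, 0]), TETRAD_LOADINGS, atol=1e-4)
        assert sol.fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert sol.fit.df == 0

    def test_population_two_factor_recovery(self):
        lam = np.zeros((8, 2))
        lam[:4, 0] = [0.8, 0.75, 0.7, 0.65]
        lam[4:, 1] = [0.8, 0.75, 0.7, 0.65]
        phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        sigma = population_corr(lam, phi)
        sol = facengine.ml_efa(sigma, 2, n=1000)
        rot = facengine.geomin_rotate(sol, seed=0)
        aligned, _ = facengine.align_to_reference(rot.loadings, rot.factor_corr, lam)
        assert np.abs(aligned - lam).max() < 0.03

    def test_degrees_of_freedom_formula(self):
        data = clean_two_factor(n=400, seed=4)
        sol = facengine.ml_efa(data, 2)
        p, k = 8, 2
        assert sol.fit.df == ((p - k) ** 2 - p - k) // 2
        assert sol.fit.df_baseline == p * (p - 1) // 2

    def test_agrees_with_reference_implementation(self):
        data = clean_two_factor(n=800, seed=6)
        sol = facengine.ml_efa(data, 2)
        ref = FactorAnalysis(n_components=2, svd_method="lapack").fit(
            (data.values - data.values.mean(0)) / data.values.std(0)
        )
        ref_common = ref.components_.T @ ref.components_
        ours = sol.loadings @ sol.factor_corr @ sol.loadings.T
        off = ~np.eye(8, dtype=bool)
        assert np.abs(ours - ref_common)[off].max() < 0.02

    def test_uniqueness_floor_flags_heywood(self):
        # a near-singular block forces a uniqueness onto the floor
        lam = np.zeros((4, 1))
        lam[:, 0] = [0.995, 0.9, 0.5, 0.4]
        sigma = population_corr(lam, np.eye(1))
        sol = facengine.ml_efa(sigma, 1, n=300)
        assert sol.uniquenesses.min() >= facengine.UNIQUENESS_FLOOR - 1e-12


class TestRotation:
    def test_rotation_preserves_fit_and_common_part(self):
        data = clean_two_factor(n=500, seed=8)
        sol = facengine.ml_efa(data, 2)
        rot = facengine.geomin_rotate(sol, seed=1)
        assert rot.fit == sol.fit
        before = sol.loadings @ sol.factor_corr @ sol.loadings.T
        after = rot.loadings @ rot.factor_corr @ rot.loadings.T
        assert np.abs(before - after).max() < 1e-8

    def test_alignment_undoes_permutation_and_sign(self):
        rng = np.random.default_rng(5)
        lam = rng.uniform(0.4, 0.8, size=(9, 3)) * (rng.random((9, 3)) < 0.4)
        lam[np.arange(9), np.repeat(np.arange(3), 3)] = 0.7
        phi = np.eye(3)
        scrambled = lam[:, [2, 0, 1]] * np.array([-1.0, 1.0, -1.0])
        aligned, _ = facengine.align_to_reference(scrambled, phi, lam)
        assert np.allclose(aligned, lam)

    def test_tucker_congruence_bounds(self):
        v = np.array([0.7, 0.6, 0.5])
        assert facengine.tucker_congruence(v, v) == pytest.approx(1.0)
        assert facengine.tucker_congruence(v, -v) == pytest.approx(-1.0)


class TestFactorCountRules:
    def test_parallel_analysis_on_four_factor_sample(self):
        spec = build_loading_matrix(study_model_spec("model1", 0.3), seed=0)
        data = simulate_dataset(spec, 500, seed=1)
        assert facengine.parallel_analysis(data, seed=0) == 4

    def test_parallel_analysis_on_noise_returns_floor(self):
        data = Dataset(
            np.random.default_rng(7).standard_normal((400, 10)),
            [f"v{i}" for i in range(10)],
        )
        assert facengine.parallel_analysis(data, seed=0) == 1

    def test_ega_recovers_two_communities(self):
        data = clean_two_factor(n=500, seed=10, per_factor=5)
        assert facengine.ega_factor_count(data, seed=0) == 2


class TestCFA:
    def test_tetrad_oracle_exact_recovery(self):
        structure = {"X1": "F1", "X2": "F1", "X3": "F1"}
        res = facengine.cfa_fit(None, structure, n=500, corr=TETRAD_CORR)
        est = np.array([res.loadings[v] for v in ("X1", "X2", "X3")])
        assert np.allclose(est, TETRAD_LOADINGS, atol=1e-4)
        assert res.fit.chi2 == pytest.approx(0.0, abs=1e-5)
        assert res.converged

    def test_two_factor_population_recovers_interfactor_r(self):
        lam = np.zeros((8, 2))
        lam[:4, 0] = 0.7
        lam[4:, 1] = 0.7
        phi = np.array([[1.0, 0.4], [0.4, 1.0]])
        sigma = population_corr(lam, phi)
        names = [f"X{i + 1}" for i in range(8)]
        structure = {v: ("F1" if i < 4 else "F2") for i, v in enumerate(names)}
        res = facengine.cfa_fit(None, structure, n=2000, corr=sigma)
        off = res.factor_corr[0, 1]
        assert off == pytest.approx(0.4, abs=0.01)
        assert res.fit.cfi > 0.999
        assert res.fit.df == 8 * 9 // 2 - 16 - 1

    def test_misspecified_structure_shows_misfit(self):
        data = clean_two_factor(n=800, seed=12)
        names = data.variable_names
        # swap two indicators across factors
        structure = {v: ("F1" if i < 4 else "F2") for i, v in enumerate(names)}
        structure[names[0]], structure[names[4]] = "F2", "F1"
        good = facengine.cfa_fit(
            data, {v: ("F1" if i < 4 else "F2") for i, v in enumerate(names)}
        )
        bad = facengine.cfa_fit(data, structure)
        assert bad.fit.cfi < good.fit.cfi
        assert bad.fit.rmsea > good.fit.rmsea

    def test_under_identified_structures_rejected(self):
        with pytest.raises(ValueError):
            facengine.cfa_fit(None, {"X1": "F1", "X2": "F1"}, n=100, corr=np.eye(2))
        structure = {"X1": "F1", "X2": "F1", "X3": "F2"}
        with pytest.raises(ValueError):
            facengine.cfa_fit(None, structure, n=100, corr=np.eye(3))
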