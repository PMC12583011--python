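"""Population model construction and data generation."""

import numpy as np
import pytest

from rfas.synthgen import (
    COMPLEX_RANGE,
    Dataset,
    FactorModelSpec,
    HeywoodError,
    STUDY_MODELS,
    build_loading_matrix,
    residual_variance,
    simulate_dataset,
    split_subsamples,
    study_model_spec,
)


def spec_40(**overrides) -> FactorModelSpec:
    base = dict(
        n_factors=4,
        n_variables=40,
        primaries_per_factor=[10, 10, 10, 10],
        structure="approximate_simple",
        mean_primary=0.56,
        mean_secondary=0.08,
        interfactor_r=0.3,
    )
    base.update(overrides)
    return FactorModelSpec(**base)


class TestResidualVariance:
    def test_orthogonal_single_loading(self):
        assert residual_variance([0.6, 0.0], np.eye(2)) == pytest.approx(0.64)

    def test_correlated_factors_reduce_residual(self):
        phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        # 1 − (0.25 + 0.09 + 2·0.5·0.3·0.3) = 0.57
        assert residual_variance([0.5, 0.3], phi) == pytest.approx(0.57)

    def test_heywood_row_raises(self):
        phi = np.array([[1.0, 0.6], [0.6, 1.0]])
        with pytest.raises(HeywoodError):
            residual_variance([0.9, 0.9], phi)

    def test_loading_magnitude_validated(self):
        with pytest.raises(ValueError):
            residual_variance([1.2, 0.0], np.eye(2))


class TestSpecValidation:
    def test_primary_counts_must_sum_to_variables(self):
        with pytest.raises(ValueError):
            spec_40(primaries_per_factor=[10, 10, 10, 9])

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            spec_40(structure="bifactor")

    def test_interfactor_r_bounded(self):
        with pytest.raises(ValueError):
            spec_40(interfactor_r=1.0)

    def test_primary_factor_layout(self):
        spec = study_model_spec("model3", 0.3)
        assert spec.primaries_per_factor == [17, 5, 2, 2]
        owners = spec.primary_factor
        assert list(owners[:17]) == [0] * 17
        assert list(owners[-2:]) == [3, 3]


class TestBuildLoadingMatrix:
    def test_mean_primary_and_secondary_match_summary_exactly(self):
        spec = build_loading_matrix(spec_40(), seed=7)
        lam = spec.loading_matrix
        owners = spec.primary_factor
        primaries = lam[np.arange(40), owners]
        secondaries = np.array(
            [lam[i, f] for i in range(40) for f in range(4) if f != owners[i]]
        )
        assert primaries.mean() == pytest.approx(0.56, abs=1e-10)
        assert np.abs(secondaries).mean() == pytest.approx(0.08, abs=1e-10)

    def test_implied_matrix_is_a_correlation_matrix(self):
        for seed in (0, 1, 2):
            spec = build_loading_matrix(spec_40(), seed=seed)
            implied = spec.implied_corr()
            assert np.allclose(np.diag(implied), 1.0)
            assert np.linalg.eigvalsh(implied).min() > 0
            assert spec.residuals.min() > 0

    def test_complex_structure_plants_large_secondaries(self):
        spec = build_loading_matrix(study_model_spec("model5", 0.3), seed=3)
        lam, owners = spec.loading_matrix, spec.primary_factor
        big = []
        for i in range(spec.n_variables):
            sec = np.abs([lam[i, f] for f in range(4) if f != owners[i]])
            big.extend(s for s in sec if s >= COMPLEX_RANGE[0])
        # 25% of 40 variables receive one large secondary each
        assert len(big) == 10
        assert all(COMPLEX_RANGE[0] <= s <= COMPLEX_RANGE[1] for s in big)

    def test_reproducible_for_a_seed(self):
        a = build_loading_matrix(spec_40(), seed=11)
        b = build_loading_matrix(spec_40(), seed=11)
        assert np.array_equal(a.loading_matrix, b.loading_matrix)

    def test_mean_primary_must_exceed_mean_secondary(self):
        with pytest.raises(ValueError):
            build_loading_matrix(
                spec_40(mean_primary=0.5, mean_secondary=0.5), seed=0
            )


class TestSimulateDataset:
    def test_shape_names_and_reproducibility(self):
        spec = build_loading_matrix(spec_40(), seed=1)
        data = simulate_dataset(spec, 300, seed=5)
        again = simulate_dataset(spec, 300, seed=5)
        assert data.n == 300 and data.p == 40
        assert data.variable_names == [f"X{i + 1}" for i in range(40)]
        assert np.array_equal(data.values, again.values)

    def test_sample_correlations_approach_population(self):
        spec = build_loading_matrix(spec_40(), seed=2)
        data = simulate_dataset(spec, 5000, seed=9)
        err = np.abs(data.corr() - spec.implied_corr())
        assert err.max() < 0.08

    def test_n_below_p_rejected(self):
        spec = build_loading_matrix(spec_40(), seed=1)
        with pytest.raises(ValueError):
            simulate_dataset(spec, 20, seed=0)


class TestSplits:
    @pytest.mark.parametrize(
        "n,frac,n_train,n_valid",
        [(300, 0.66, 198, 102), (500, 0.66, 330, 170), (1000, 0.66, 660, 340), (500, 0.70, 350, 150)],
    )
    def test_split_sizes(self, n, frac, n_train, n_valid):
        data = Dataset(np.random.default_rng(0).standard_normal((n, 4)), list("abcd"))
        train, valid = split_subsamples(data, 1, frac, seed=0)[0]
        assert len(train) == n_train and len(valid) == n_valid

    def test_partitions_are_disjoint_and_exhaustive(self):
        data = Dataset(np.random.default_rng(1).standard_normal((97, 5)), list("abcde"))
        for train, valid in split_subsamples(data, 5, 0.66, seed=3):
            combined = np.concatenate([train, valid])
            assert len(np.unique(combined)) == 97

    def test_training_must_cover_variables(self):
        data = Dataset(np.random.default_rng(2).standard_normal((10, 8)), [f"v{i}" for i in range(8)])
        with pytest.raises(ValueError):
            split_subsamples(data, 1, 0.5, seed=0)


class TestDataset:
    def test_subset_and_rows(self):
        data = Dataset(np.arange(12.0).reshape(4, 3), ["a", "b", "c"])
        sub = data.subset(["c", "a", "b"])
        assert sub.variable_names == ["c", "a", "b"]
        assert np.array_equal(sub.values[:, 1], data.values[:, 0])
        rows = data.rows(np.array([0, 2]))
        assert rows.n == 2 and np.array_equal(rows.values[1], data.values[2])

    def test_csv_round_trip(self, tmp_path):
        data = Dataset(np.random.default_rng(3).standard_normal((6, 3)), ["x", "y", "z"])
        path = tmp_path / "d.csv"
        data.to_csv(path)
        back = Dataset.from_csv(path)
        assert back.variable_names == data.variable_names
        assert np.allclose(back.values, data.values)

    def test_missing_values_rejected(self):
        values = np.ones((5, 3))
        values[0, 0] = np.nan
        with pytest.raises(ValueError):
            Dataset(values, ["a", "b", "c"])


def test_study_model_catalogue_is_consistent():
    assert set(STUDY_MODELS) == {f"model{i}" for i in range(1, 7)}
    for name in STUDY_MODELS:
        spec = study_model_spec(name, 0.3)
        assert sum(spec.primaries_per_factor) == spec.n_variables
        assert spec.mean_primary > spec.mean_secondary
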