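import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from splicedyn.developmental_dynamics import (
    call_devses,
    devse_fraction,
    fit_quasibinomial_glm,
    natural_spline_basis,
    qlrt_devtest,
    quasi_f_test,
)
from splicedyn.psi_quant import PsiMatrix, compute_psi, impute_missing
from splicedyn.synthetic_data import NoiseParams, PsiModel, simulate_junction_counts

from conftest import make_event


def simulate_psi(models, metadata, seed, noise=NoiseParams(100.0, 30.0, 0.02, 0.0)):
    counts, _ = simulate_junction_counts(len(models), metadata, models, noise, seed=seed)
    return impute_missing(compute_psi(counts, metadata=metadata))


class TestGlmFit:
    def test_two_level_saturated_closed_form(self):
        # intercept = logit(p1), effect = logit(p2) - logit(p1)
        y = np.array([0.2, 0.2, 0.2, 0.6, 0.6, 0.6])
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_quasibinomial_glm(y, X)
        assert fit.coefficients[0] == pytest.approx(logit(0.2), abs=1e-6)
        assert fit.coefficients[1] == pytest.approx(logit(0.6) - logit(0.2), abs=1e-6)

    def test_dispersion_near_one_under_binomial(self):
        rng = np.random.default_rng(31)
        n, totals = 100, 500
        x = rng.normal(size=n)
        mu = 1 / (1 + np.exp(-(0.2 + 0.5 * x)))
        y = rng.binomial(totals, mu) / totals
        X = np.column_stack([np.ones(n), x])
        fit = fit_quasibinomial_glm(y, X, weights=np.full(n, float(totals)))
        assert 0.8 <= fit.dispersion <= 1.2

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(32)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            totals = rng.integers(20, 200, size=n).astype(float)
            mu = 1 / (1 + np.exp(-(rng.normal() + rng.normal() * X[:, 1])))
            y = rng.binomial(totals.astype(int), mu) / totals
            fit = fit_quasibinomial_glm(y, X, weights=totals)
            oracle = sm.GLM(
                y, X, family=sm.families.Binomial(), var_weights=totals
            ).fit()
            np.testing.assert_allclose(fit.coefficients, oracle.params, atol=1e-6)
            assert fit.deviance == pytest.approx(oracle.deviance, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        y = np.array([0.1, 0.5, 0.9, 0.3])
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_quasibinomial_glm(y, X)

    def test_response_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            fit_quasibinomial_glm(np.array([0.5, 1.2]), np.ones((2, 1)))

    def test_full_deviance_below_null(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            n = 20
            y = rng.uniform(0.05, 0.95, n)
            X_full = np.column_stack([np.ones(n), rng.normal(size=n)])
            null = fit_quasibinomial_glm(y, np.ones((n, 1)))
            full = fit_quasibinomial_glm(y, X_full)
            assert full.deviance <= null.deviance + 1e-8


class TestNaturalSplineBasis:
    def test_shape_and_rank(self):
        x = np.arange(1.0, 28.0)
        basis = natural_spline_basis(x, 3)
        assert basis.shape == (27, 3)
        assert np.linalg.matrix_rank(np.column_stack([np.ones(27), basis])) == 4

    def test_df_one_is_linear(self):
        x = np.arange(5.0)
        np.testing.assert_array_equal(natural_spline_basis(x, 1), x[:, None])

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            natural_spline_basis(np.array([1.0, 2.0, 1.0]), 3)


class TestQlrtDevtest:
    def test_two_level_equivalence_with_group_test(self, two_group_metadata):
        # a 2-level stage factor must reproduce the two-group machinery
        from splicedyn.differential_splicing import test_two_group
        from splicedyn.io_formats import SampleMetadata

        metadata = [
            SampleMetadata(m.sample_id, group=m.group,
                           stage=1.0 if m.group == "GM" else 2.0)
            for m in two_group_metadata
        ]
        psi = simulate_psi(
            [PsiModel("group_shift", base_psi=0.3, delta=0.2)] * 5, metadata, seed=41
        )
        with pytest.raises(ValueError, match="3 distinct"):
            qlrt_devtest(psi)
        # 3 distinct stages with df capped at 2 still nests the group split;
        # exact equivalence needs matching designs, so compare on 2 levels by
        # relaxing the guard through a 3-level layout collapsed to 2 groups.
        group_p = test_two_group(psi)["pvalue"].to_numpy()
        stages = np.array([m.stage for m in metadata])
        from splicedyn.developmental_dynamics import (
            fit_quasibinomial_glm,
            quasi_f_test,
            _evidence_weights,
        )

        weights = _evidence_weights(psi)
        for i in range(len(psi.events)):
            y = psi.psi[i]
            w = weights[i]
            X = np.column_stack([np.ones(stages.size), stages])
            null = fit_quasibinomial_glm(y, np.ones((stages.size, 1)), w)
            full = fit_quasibinomial_glm(y, X, w)
            _, _, _, p = quasi_f_test(null, full)
            assert p == pytest.approx(group_p[i], abs=1e-10)

    def test_planted_trajectory_detected(self, stage_metadata):
        models = [
            PsiModel("logistic_trajectory", base_psi=0.2, delta=0.6,
                     midpoint=14.0, slope=0.5)
        ] * 50
        psi = simulate_psi(models, stage_metadata, seed=42)
        results = call_devses(qlrt_devtest(psi))
        assert results.is_devse.mean() >= 0.9

    def test_permuted_stages_give_uniform_pvalues(self, stage_metadata):
        models = [PsiModel("logistic_trajectory", base_psi=0.2, delta=0.6,
                           midpoint=14.0, slope=0.5)]
        psi = simulate_psi(models, stage_metadata, seed=43)
        rng = np.random.default_rng(44)
        stages = np.array([m.stage for m in stage_metadata])
        pvalues = []
        for _ in range(300):
            permuted = rng.permutation(stages)
            pvalues.append(qlrt_devtest(psi, stages=permuted)["pvalue"][0])
        ks = stats.kstest(pvalues, "uniform")
        assert ks.pvalue > 0.001
        assert 0.4 < np.mean(pvalues) < 0.6

    def test_dispersion_increases_with_rho(self, stage_metadata):
        medians = []
        for rho in (0.0, 0.05, 0.15):
            psi = simulate_psi(
                [PsiModel("constant", base_psi=0.5)] * 100,
                stage_metadata,
                seed=45,
                noise=NoiseParams(100.0, 30.0, rho, 0.0),
            )
            medians.append(qlrt_devtest(psi)["dispersion"].median())
        assert medians[0] < medians[1] < medians[2]

    def test_constant_event_pvalue_one(self, stage_metadata):
        matrix = PsiMatrix(
            events=[make_event("e0")],
            sample_ids=[m.sample_id for m in stage_metadata],
            psi=np.full((1, len(stage_metadata)), 0.4),
            missing_mask=np.zeros((1, len(stage_metadata)), dtype=bool),
            metadata=stage_metadata,
        )
        assert qlrt_devtest(matrix)["pvalue"][0] == 1.0

    def test_too_few_stages_rejected(self):
        from splicedyn.io_formats import SampleMetadata

        metadata = [SampleMetadata(f"s{i}", stage=float(i % 2)) for i in range(8)]
        matrix = PsiMatrix(
            events=[make_event("e0")],
            sample_ids=[m.sample_id for m in metadata],
            psi=np.random.default_rng(0).uniform(0.2, 0.8, (1, 8)),
            missing_mask=np.zeros((1, 8), dtype=bool),
            metadata=metadata,
        )
        with pytest.raises(ValueError, match="3 distinct"):
            qlrt_devtest(matrix)


class TestCallDevses:
    @staticmethod
    def frame(adjusted):
        return pd.DataFrame(
            {
                "event_id": [f"e{i}" for i in range(len(adjusted))],
                "pvalue": adjusted,
                "adjusted_pvalue": adjusted,
            }
        )

    def test_boundary_inclusive(self):
        assert call_devses(self.frame([0.05])).is_devse[0]

    def test_just_above_boundary_not_called(self):
        assert not call_devses(self.frame([0.051])).is_devse[0]

    def test_fraction_report(self):
        adjusted = [0.01] * 3253 + [0.5] * (9071 - 3253)
        results = call_devses(self.frame(adjusted))
        from splicedyn.io_formats import round_percentage

        assert round_percentage(devse_fraction(results), 2) == 35.86
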