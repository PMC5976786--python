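"""Path-model structure, outlier exclusion, ML estimation, fit indices."""

import numpy as np
import pandas as pd
import pytest

from elicse import (
    ConditioningError,
    DegeneracyError,
    EMODEB_VARIABLES,
    PathModel,
    ScoreRow,
    ScoreTable,
    StructureError,
    emodeb_model,
    fit_indices,
    fit_path_model,
    follow_up_regression,
    mahalanobis_filter,
    model_df,
)
from elicse.simulate import ScoreSimConfig, simulate_scores


def table_from_matrix(x, variables=EMODEB_VARIABLES):
    rows = [
        ScoreRow(
            session_id=f"s{i}",
            participant_id="p1",
            **{v: float(x[i, j]) for j, v in enumerate(variables)},
        )
        for i in range(x.shape[0])
    ]
    return ScoreTable(rows=rows)


def ols_oracle(model, x, variables):
    """Independent equation-wise least squares on the raw data matrix."""
    idx = {v: j for j, v in enumerate(variables)}
    xc = x - x.mean(axis=0)
    estimates = {}
    for child in model.endogenous:
        parents = model.parents(child)
        design = xc[:, [idx[p] for p in parents]]
        beta, *_ = np.linalg.lstsq(design, xc[:, idx[child]], rcond=None)
        for p, b in zip(parents, beta):
            estimates[(p, child)] = b
    return estimates


class TestStructure:
    def test_emodeb_shape(self):
        m = emodeb_model()
        assert len(m.edges) == 9
        assert m.exogenous == {"GAct"}
        assert set(m.parents("RoAct_qogest")) == {"RoAct", "LTAct_postsup", "GAct_gsup"}
        assert m.topological_order()[0] == "GAct"

    def test_cycle_rejected(self):
        with pytest.raises(StructureError, match="cycle"):
            PathModel(
                variables=("a", "b"),
                edges=(("a", "b"), ("b", "a")),
                exogenous=frozenset(),
            )

    def test_model_df_emodeb(self):
        assert model_df(emodeb_model()) == 6

    def test_model_df_saturated(self):
        # fully recursive model on 6 variables: 15 edges, df = 0
        variables = EMODEB_VARIABLES
        edges = tuple(
            (variables[i], variables[j])
            for j in range(6)
            for i in range(j)
        )
        m = PathModel(variables=variables, edges=edges, exogenous=frozenset({variables[0]}))
        assert model_df(m) == 0

    def test_model_df_independence(self):
        m = PathModel(variables=EMODEB_VARIABLES, edges=(), exogenous=frozenset(EMODEB_VARIABLES))
        assert model_df(m) == 15

    def test_df_accounting_totals_21(self):
        m = emodeb_model()
        free = len(m.edges) + len(m.exogenous) + len(m.endogenous)
        assert model_df(m) + free == 21


class TestMahalanobis:
    def test_row_at_centroid_never_first_out(self, rng):
        x = rng.normal(size=(30, 6)) * 5 + 10
        x[0] = x.mean(axis=0)  # plant a row (almost) at the centroid
        table = table_from_matrix(x)
        _, report = mahalanobis_filter(table, k=5)
        d2 = report.distances.to_numpy()
        assert np.argmin(d2) == 0
        assert ("s0", "p1") not in report.excluded_keys

    def test_far_row_excluded_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 6))
        x[7] += 30.0  # planted outlier
        table = table_from_matrix(x)
        kept, report = mahalanobis_filter(table, k=1)
        assert report.excluded_keys == [("s7", "p1")]
        assert len(kept) == 39

    def test_fixed_k_seven_of_84(self, rng):
        x = rng.normal(size=(84, 6))
        kept, report = mahalanobis_filter(table_from_matrix(x), k=7)
        assert len(kept) == 77
        assert len(report.excluded_keys) == 7

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(50, 6))
        A = rng.normal(size=(6, 6)) + np.eye(6) * 3
        shift = rng.normal(size=6) * 10
        t1 = table_from_matrix(x)
        t2 = table_from_matrix(x @ A.T + shift)
        _, r1 = mahalanobis_filter(t1, k=3)
        _, r2 = mahalanobis_filter(t2, k=3)
        np.testing.assert_allclose(
            r1.distances.to_numpy(), r2.distances.to_numpy(), rtol=1e-8
        )

    def test_singular_covariance_rejected(self, rng):
        x = rng.normal(size=(30, 6))
        x[:, 5] = x[:, 4]  # collinear
        with pytest.raises(ConditioningError):
            mahalanobis_filter(table_from_matrix(x), k=1)


class TestFit:
    def test_ml_equals_ols_on_random_data(self, rng):
        m = emodeb_model()
        worst = 0.0
        for _ in range(10):
            n = int(rng.integers(50, 500))
            cov = rng.normal(size=(6, 6))
            cov = cov @ cov.T + np.eye(6)
            x = rng.multivariate_normal(np.zeros(6), cov, size=n)
            fit = fit_path_model(m, table_from_matrix(x))
            oracle = ols_oracle(m, x, EMODEB_VARIABLES)
            worst = max(
                worst,
                max(abs(fit.estimates[e] - oracle[e]) for e in m.edges),
            )
        assert worst < 1e-6

    def test_saturated_model_perfect_fit(self, rng):
        variables = EMODEB_VARIABLES
        edges = tuple((variables[i], variables[j]) for j in range(6) for i in range(j))
        m = PathModel(variables=variables, edges=edges, exogenous=frozenset({variables[0]}))
        x = rng.normal(size=(100, 6))
        fit = fit_path_model(m, table_from_matrix(x))
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_standardized_estimates_scale_free(self, rng):
        m = emodeb_model()
        tbl, _ = simulate_scores(ScoreSimConfig(n=300, seed=11))
        x = tbl.to_frame()[list(EMODEB_VARIABLES)].to_numpy()
        f1 = fit_path_model(m, table_from_matrix(x))
        f2 = fit_path_model(m, table_from_matrix(x * 7.5))
        for e in m.edges:
            assert f1.std_estimates[e] == pytest.approx(f2.std_estimates[e], abs=1e-8)

    def test_se_matches_ols_standard_error(self, rng):
        # for a single-parent equation the information-based SE should agree
        # with the classical regression SE up to O(1/n)
        m = PathModel(
            variables=("x", "y"), edges=(("x", "y"),), exogenous=frozenset({"x"})
        )
        n = 400
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n) * 0.8
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_path_model(m, df)
        resid = y - fit.estimates[("x", "y")] * x
        se_ols = np.std(resid, ddof=1) / (np.std(x, ddof=1) * np.sqrt(n - 1))
        assert fit.se[("x", "y")] == pytest.approx(se_ols, rel=0.05)

    def test_too_few_rows_rejected(self, rng):
        x = rng.normal(size=(10, 6))
        with pytest.raises(DegeneracyError):
            fit_path_model(emodeb_model(), table_from_matrix(x))


class TestFitIndices:
    def test_perfect_fit_limits(self):
        r = fit_indices(chi2=6.0, df=6, chi2_null=300.0, df_null=15, n=77)
        assert r.rmsea == 0.0
        assert r.cfi == 1.0

    def test_zero_chi2_gives_nfi_one(self):
        r = fit_indices(chi2=0.0, df=6, chi2_null=300.0, df_null=15, n=77)
        assert r.nfi == 1.0

    def test_hand_arithmetic(self):
        r = fit_indices(chi2=30.0, df=6, chi2_null=300.0, df_null=15, n=101)
        assert r.rmsea == pytest.approx(0.200)
        assert r.nfi == pytest.approx(0.900)
        assert r.rfi == pytest.approx(1 - (30 / 6) / (300 / 15))
        assert r.pnfi == pytest.approx((6 / 15) * 0.9)

    def test_degenerate_null_rejected(self):
        with pytest.raises(DegeneracyError):
            fit_indices(chi2=1.0, df=6, chi2_null=0.0, df_null=15, n=77)


class TestFollowUpRegression:
    def test_perfect_relation(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        r = follow_up_regression("a", "b", df)
        assert r.beta_std == pytest.approx(1.0)
        assert r.p == pytest.approx(0.0, abs=1e-12)

    def test_null_relation_small_beta(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        r = follow_up_regression("a", "b", df)
        assert abs(r.beta_std) < 0.05

    def test_closed_form_t_statistic(self):
        # construct data with exactly beta_std = 0.246 at n = 77
        n, r_target = 77, 0.246
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)  # orthogonalize
        z /= z.std(ddof=1)
        y = r_target * x + np.sqrt(1 - r_target**2) * z
        res = follow_up_regression("x", "y", pd.DataFrame({"x": x, "y": y}))
        assert res.beta_std == pytest.approx(0.246, abs=1e-9)
        assert res.df == 75
        assert res.t == pytest.approx(2.199, abs=5e-3)
        assert res.p < 0.05

    def test_zero_variance_predictor_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(DegeneracyError):
            follow_up_regression("a", "b", df)
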