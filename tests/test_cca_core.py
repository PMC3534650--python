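import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import annotation, em
from oracles import align_signs, cca_brute_force, weighted_pearson
from ccam.cca_core import (
    EnvironmentMatrix,
    build_environment,
    cca_fit,
    check_env_collinearity,
    chi_square_form,
    decompose_inertia,
    env_arrow_scores,
    percent_visualised,
)


def _random_instance(rng, n=None, m=None, k=None):
    n = n or int(rng.integers(5, 11))
    m = m or int(rng.integers(4, 7))
    k = k or int(rng.integers(1, min(4, m)))
    X = rng.uniform(0.2, 3.0, size=(n, m))
    Z = rng.normal(size=(n, k))
    x = em(X)
    env = EnvironmentMatrix(x.gene_ids, [f"p{j}" for j in range(k)], Z)
    return x, env


class TestChiSquareForm:
    def test_masses_sum_to_one(self):
        form = chi_square_form(np.random.default_rng(0).uniform(1, 2, (6, 4)))
        assert form.P.sum() == pytest.approx(1.0)
        assert form.r.sum() == pytest.approx(1.0)
        assert form.c.sum() == pytest.approx(1.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="shift_nonnegative"):
            chi_square_form(np.array([[1.0, -0.5], [2.0, 3.0]]))

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="gene rows"):
            chi_square_form(np.array([[0.0, 0.0], [2.0, 3.0]]))


class TestBuildEnvironment:
    def test_single_sample_population(self):
        x = em(np.arange(8, dtype=float).reshape(4, 2))
        ann = annotation(x.sample_ids, ["A", "B"])
        env = build_environment(x, ann, ["A", "B"])
        np.testing.assert_array_equal(env.Z[:, 0], x.values[:, 0])

    def test_identical_samples_idempotent_mean(self):
        col = np.array([1.0, 2.0, 3.0])
        x = em(np.column_stack([col, col]))
        ann = annotation(x.sample_ids, ["A", "A"])
        env = build_environment(x, ann, ["A"])
        np.testing.assert_array_equal(env.Z[:, 0], col)

    def test_matches_group_means(self):
        rng = np.random.default_rng(1)
        x = em(rng.normal(size=(10, 12)))
        groups = [f"P{j}" for j in range(4) for _ in range(3)]
        ann = annotation(x.sample_ids, groups)
        env = build_environment(x, ann)
        for j, pop in enumerate(env.population_ids):
            cols = [i for i, g in enumerate(groups) if g == pop]
            np.testing.assert_allclose(
                env.Z[:, j], x.values[:, cols].mean(axis=1)
            )

    def test_unknown_population_error(self):
        x = em(np.ones((3, 2)) + np.arange(6).reshape(3, 2))
        ann = annotation(x.sample_ids, ["A", "B"])
        with pytest.raises(ValueError, match="nope"):
            build_environment(x, ann, ["nope"])


class TestCollinearity:
    def test_duplicate_column_flagged(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(20, 1))
        env = EnvironmentMatrix(
            [f"g{i}" for i in range(20)], ["a", "b"], np.hstack([z, z])
        )
        report = check_env_collinearity(env)
        assert ("a", "b", pytest.approx(1.0)) in report.flagged_pairs

    def test_orthogonal_columns_vif_one(self):
        n = 40
        q, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(n, 3)))
        env = EnvironmentMatrix([f"g{i}" for i in range(n)], ["a", "b", "c"], q)
        report = check_env_collinearity(env)
        assert report.ok
        assert np.allclose(report.vif.to_numpy(), 1.0, atol=0.2)

    def test_exact_dependence_reports_singular(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(25, 2))
        env = EnvironmentMatrix(
            [f"g{i}" for i in range(25)],
            ["a", "b", "c"],
            np.hstack([z, z.sum(axis=1, keepdims=True)]),
        )
        report = check_env_collinearity(env)
        assert np.isinf(report.vif.to_numpy()).all()


class TestCCAFit:
    def test_independence_table_null_inertia(self):
        r = np.array([0.1, 0.3, 0.6])
        c = np.array([0.2, 0.3, 0.5])
        X = 100 * np.outer(r, c)
        x = em(X)
        env = EnvironmentMatrix(x.gene_ids, ["p"], np.array([[1.0], [2.0], [5.0]]))
        form = chi_square_form(X)
        assert (form.Qbar**2).sum() == pytest.approx(0.0, abs=1e-18)
        with pytest.raises(ValueError, match="null"):
            cca_fit(x, env)

    def test_ca_reduction_full_span(self):
        # environment spanning Qbar's column space: projection is the
        # identity there, so CCA must reproduce plain CA
        rng = np.random.default_rng(5)
        X = rng.uniform(0.5, 2.0, size=(6, 4))
        form = chi_square_form(X)
        U, lam, _ = np.linalg.svd(form.Qbar, full_matrices=False)
        rank = int((lam > 1e-10 * lam[0]).sum())
        Z = U[:, :rank] / np.sqrt(form.r)[:, None]
        x = em(X)
        env = EnvironmentMatrix(x.gene_ids, [f"p{j}" for j in range(rank)], Z)
        res = cca_fit(x, env)
        assert res.percent_explained == pytest.approx(100.0, abs=1e-8)
        np.testing.assert_allclose(
            res.eigenvalues, lam[:rank] ** 2, atol=1e-12
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        x, env = _random_instance(rng, n=6, m=4, k=2)
        res = cca_fit(x, env, scaling=0)
        o = cca_brute_force(x.values, env.Z)
        np.testing.assert_allclose(res.eigenvalues, o["eigenvalues"], atol=1e-10)
        for mine, theirs in [
            (res.gene_scores_lc.to_numpy(), o["U0"]),
            (res.sample_scores.to_numpy(), o["V0"]),
            (res.gene_scores_wa.to_numpy(), o["wa"]),
            (res.env_biplot.to_numpy(), o["B"]),
        ]:
            np.testing.assert_allclose(align_signs(mine, theirs), mine, atol=1e-10)

    def test_overfit_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0.5, 2.0, size=(8, 3))
        x = em(X)
        env = EnvironmentMatrix(
            x.gene_ids, ["a", "b", "c"], rng.normal(size=(8, 3))
        )
        with pytest.raises(ValueError, match="overfit"):
            cca_fit(x, env)

    def test_dependent_env_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.5, 2.0, size=(8, 5))
        z = rng.normal(size=(8, 1))
        x = em(X)
        env = EnvironmentMatrix(x.gene_ids, ["a", "b"], np.hstack([z, 2 * z]))
        with pytest.raises(ValueError, match="collinearity"):
            cca_fit(x, env)

    def test_negative_entries_rejected(self):
        x = em(np.array([[1.0, -1.0], [2.0, 3.0], [1.0, 1.0]]))
        env = EnvironmentMatrix(x.gene_ids, ["a"], np.arange(3.0)[:, None])
        with pytest.raises(ValueError, match="shift_nonnegative"):
            cca_fit(x, env)

    def test_scaling_options(self):
        rng = np.random.default_rng(9)
        x, env = _random_instance(rng, n=8, m=5, k=2)
        r0 = cca_fit(x, env, scaling=0)
        r1 = cca_fit(x, env, scaling=1)
        r2 = cca_fit(x, env, scaling=2)
        lam = r0.lambdas
        np.testing.assert_allclose(
            r1.gene_scores_lc.to_numpy(), r0.gene_scores_lc.to_numpy() * lam
        )
        np.testing.assert_allclose(
            r2.sample_scores.to_numpy(), r0.sample_scores.to_numpy() * lam
        )
        np.testing.assert_allclose(r0.eigenvalues, r2.eigenvalues)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        x, env = _random_instance(rng)
        res1 = cca_fit(x, env)
        res2 = cca_fit(em(x.values * 37.5), env)
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-12)
        np.testing.assert_allclose(
            res1.sample_scores.to_numpy(),
            res2.sample_scores.to_numpy(),
            atol=1e-10,
        )
        assert res1.inertia_total == pytest.approx(res2.inertia_total)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(11)
        x, env = _random_instance(rng)
        res = cca_fit(x, env)
        B = res.env_biplot.to_numpy()
        for k in range(res.n_axes):
            assert B[np.abs(B[:, k]).argmax(), k] > 0

    def test_wa_lc_consistency(self):
        rng = np.random.default_rng(12)
        x, env = _random_instance(rng, n=9, m=6, k=3)
        res = cca_fit(x, env, scaling=0)
        Zw = np.sqrt(res.r)[:, None] * res.Zstd
        H = Zw @ np.linalg.solve(Zw.T @ Zw, Zw.T)
        wa_w = np.sqrt(res.r)[:, None] * res.gene_scores_wa.to_numpy()
        lc_w = np.sqrt(res.r)[:, None] * res.gene_scores_lc.to_numpy()
        np.testing.assert_allclose(H @ wa_w, lc_w, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_inertia_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        x, env = _random_instance(rng)
        res = cca_fit(x, env)
        report = decompose_inertia(res)
        assert report["inertia_constrained"] + report[
            "inertia_unconstrained"
        ] == pytest.approx(report["inertia_total"], rel=1e-10)
        assert report["inertia_constrained"] <= report["inertia_total"] * (1 + 1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_monotone_in_env_columns(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 10, 6
        X = rng.uniform(0.2, 3.0, size=(n, m))
        Z = rng.normal(size=(n, 3))
        x = em(X)
        prev = -np.inf
        for k in (1, 2, 3):
            env = EnvironmentMatrix(
                x.gene_ids, [f"p{j}" for j in range(k)], Z[:, :k]
            )
            res = cca_fit(x, env)
            assert res.inertia_constrained >= prev - 1e-12
            prev = res.inertia_constrained


class TestArrowScores:
    def test_perfect_correlation_unit_arrow(self):
        rng = np.random.default_rng(13)
        x, env = _random_instance(rng, n=8, m=5, k=1)
        res = cca_fit(x, env)
        # rebuild an environment proportional to axis-1 wa scores
        wa1 = res.gene_scores_wa["Axis1"].to_numpy()
        env2 = EnvironmentMatrix(x.gene_ids, ["w"], (2.5 * wa1)[:, None])
        B = env_arrow_scores(res, env2)
        assert abs(B.loc["w", "Axis1"]) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_env_zero_arrow(self):
        rng = np.random.default_rng(14)
        x, env = _random_instance(rng, n=9, m=6, k=2)
        res = cca_fit(x, env)
        wa = res.gene_scores_wa.to_numpy()
        r = res.r
        # build a vector r-orthogonal to every axis and to the constant
        v = rng.normal(size=9)
        basis = np.column_stack([np.ones(9), wa])
        coef = np.linalg.solve(basis.T @ (r[:, None] * basis), basis.T @ (r * v))
        v = v - basis @ coef
        env2 = EnvironmentMatrix(x.gene_ids, ["o"], v[:, None])
        B = env_arrow_scores(res, env2)
        np.testing.assert_allclose(B.loc["o"].to_numpy(), 0.0, atol=1e-8)

    def test_matches_direct_weighted_pearson(self):
        rng = np.random.default_rng(15)
        x, env = _random_instance(rng, n=10, m=6, k=2)
        res = cca_fit(x, env)
        Zstd = env.standardized(res.r)
        wa = res.gene_scores_wa.to_numpy()
        for j in range(2):
            for k in range(res.n_axes):
                expected = weighted_pearson(Zstd[:, j], wa[:, k], res.r)
                assert res.env_biplot.iloc[j, k] == pytest.approx(
                    expected, abs=1e-10
                )


class TestInertiaReports:
    def test_percent_visualised_full_space(self):
        rng = np.random.default_rng(16)
        x, env = _random_instance(rng, n=8, m=6, k=3)
        res = cca_fit(x, env)
        assert percent_visualised(res, res.n_axes) == pytest.approx(100.0)

    def test_percent_visualised_arithmetic(self):
        rng = np.random.default_rng(17)
        x, env = _random_instance(rng, n=8, m=6, k=3)
        res = cca_fit(x, env)
        o = cca_brute_force(x.values, env.Z)
        expected = 100 * o["eigenvalues"][0] / o["eigenvalues"].sum()
        assert percent_visualised(res, 1) == pytest.approx(expected, rel=1e-10)

    def test_percent_visualised_bounds(self):
        rng = np.random.default_rng(18)
        x, env = _random_instance(rng, k=2)
        res = cca_fit(x, env)
        with pytest.raises(ValueError):
            percent_visualised(res, 0)
        with pytest.raises(ValueError):
            percent_visualised(res, res.n_axes + 1)

    def test_decompose_matches_oracle(self):
        rng = np.random.default_rng(19)
        X = rng.uniform(0.2, 3.0, size=(20, 8))
        Z = rng.normal(size=(20, 3))
        x = em(X)
        env = EnvironmentMatrix(x.gene_ids, ["a", "b", "c"], Z)
        res = cca_fit(x, env)
        o = cca_brute_force(X, Z)
        report = decompose_inertia(res)
        assert report["percent_explained"] == pytest.approx(
            100 * o["inertia_constrained"] / o["inertia_total"], rel=1e-10
        )

    def test_axis_fractions_sum_to_one(self):
        rng = np.random.default_rng(20)
        x, env = _random_instance(rng, k=3)
        res = cca_fit(x, env)
        assert res.axis_fractions.sum() == pytest.approx(1.0)
        assert (np.diff(res.eigenvalues) <= 1e-15).all()
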