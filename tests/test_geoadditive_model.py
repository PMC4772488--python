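"""Spline bases, graph precision, design assembly and the Gibbs sampler."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from geosba.geoadditive_model import (
    DegenerateCovariateError,
    McmcConfig,
    ModelSpec,
    bernoulli_deviance,
    build_design,
    build_spline_basis,
    default_full_spec,
    deviance,
    fit,
    fixed_term,
    graph_precision,
)
from geosba.io_types import DistrictGraph, SurveyTable
from geosba.synthetic_data import make_lattice_graph
from geosba._polya_gamma import polya_gamma_mean, random_polya_gamma


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.3, 1.0, 2.5, 6.0, 15.0])
    def test_mean_matches_closed_form(self, z):
        rng = np.random.default_rng(int(z * 10) + 1)
        draws = random_polya_gamma(np.full(60_000, z), rng)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - polya_gamma_mean(z)) < 4 * se

    def test_variance_at_zero(self):
        rng = np.random.default_rng(0)
        draws = random_polya_gamma(np.zeros(200_000), rng)
        assert draws.var() == pytest.approx(1 / 24, rel=0.03)

    def test_sign_invariance(self):
        a = random_polya_gamma(np.full(5, 2.0), np.random.default_rng(3))
        b = random_polya_gamma(np.full(5, -2.0), np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestSplineBasis:
    def test_partition_of_unity(self):
        x = np.linspace(0.0, 1.0, 300)
        basis = build_spline_basis(x, n_knots=12)
        np.testing.assert_allclose(basis.basis.sum(axis=1), 1.0, atol=1e-12)

    def test_penalty_null_space_is_polynomial(self):
        x = np.linspace(0.0, 1.0, 50)
        basis = build_spline_basis(x, n_knots=8, penalty_order=2)
        m = basis.n_coef
        # order-2 difference penalty annihilates constants and linear trends
        np.testing.assert_allclose(basis.penalty @ np.ones(m), 0.0, atol=1e-12)
        np.testing.assert_allclose(basis.penalty @ np.arange(m, dtype=float), 0.0, atol=1e-10)
        eigs = np.linalg.eigvalsh(basis.penalty)
        assert (eigs < 1e-10).sum() == 2
        assert (eigs > -1e-10).all()  # PSD

    def test_quadratic_reproduced_exactly(self):
        x = np.linspace(0.0, 2.0, 200)
        y = 3.0 * x**2 - 2.0 * x + 1.0
        basis = build_spline_basis(x, n_knots=10, degree=3)
        coef, *_ = np.linalg.lstsq(basis.basis, y, rcond=None)
        assert np.abs(basis.basis @ coef - y).max() < 1e-8

    def test_constant_covariate_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            build_spline_basis(np.ones(50))


class TestGraphPrecision:
    def test_path_graph_matrix(self):
        g = DistrictGraph(("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}),
                          {d: "" for d in "ABC"})
        k = graph_precision(g)
        np.testing.assert_array_equal(
            k, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    def test_isolated_node_zero_row(self):
        g = DistrictGraph(("A", "B", "C"), frozenset({("A", "B")}),
                          {d: "" for d in "ABC"})
        k = graph_precision(g)
        assert (k[2] == 0).all() and (k[:, 2] == 0).all()

    def test_nullity_equals_component_count(self):
        g = make_lattice_graph(5, 5)
        k = graph_precision(g)
        eigs = np.linalg.eigvalsh(k)
        assert (np.abs(eigs) < 1e-9).sum() == g.n_components == 1
        np.testing.assert_allclose(k.sum(axis=1), 0.0, atol=1e-12)


def _toy_table(y, district=None, extra=None):
    n = len(y)
    df = pd.DataFrame({"outcome": y, "district": district or ["A"] * n})
    if extra is not None:
        for k, v in extra.items():
            df[k] = v
    return SurveyTable(df, Counter())


class TestBuildDesign:
    def test_intercept_only_design_is_ones(self):
        g = DistrictGraph(("A",), frozenset(), {"A": ""})
        bundle = build_design(_toy_table([0, 1, 1]), ModelSpec(), g)
        np.testing.assert_array_equal(bundle.x_fixed, np.ones((3, 1)))

    def test_three_level_factor_gives_two_dummies(self):
        g = DistrictGraph(("A",), frozenset(), {"A": ""})
        table = _toy_table([0, 1, 1], extra={"education": ["none", "primary", "secondary+"]})
        spec = ModelSpec(fixed=(fixed_term("education"),))
        bundle = build_design(table, spec, g)
        assert bundle.fixed_names == (
            "(Intercept)",
            "education[primary]",
            "education[secondary+]",
        )

    def test_absent_level_warns_with_zero_column(self):
        g = DistrictGraph(("A",), frozenset(), {"A": ""})
        table = _toy_table([0, 1], extra={"education": ["none", "primary"]})
        spec = ModelSpec(fixed=(fixed_term("education"),))
        with pytest.warns(UserWarning, match="absent"):
            bundle = build_design(table, spec, g)
        assert (bundle.x_fixed[:, 2] == 0).all()

    def test_predictor_roundtrip_matches_generator(self, default_scenario):
        _, graph, table, truth = default_scenario
        bundle = build_design(table, default_full_spec(), graph)
        eta = bundle.assemble_eta(
            truth.fixed_effects_by_name(),
            truth.smooth_functions,
            truth.f_str,
            truth.f_unstr,
        )
        assert np.abs(eta - truth.eta).max() < 1e-10


class TestFit:
    def test_same_seed_reproducible(self):
        g = make_lattice_graph(2, 2)
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 120)
        dists = rng.choice(g.district_ids, 120)
        table = _toy_table(y.tolist(), district=dists.tolist())
        spec = ModelSpec(structured=True, unstructured=True)
        cfg = McmcConfig(iterations=300, burn_in=50, thin=2, seed=99)
        d1 = fit(build_design(table, spec, g), cfg)
        d2 = fit(build_design(table, spec, g), cfg)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.f_str, d2.f_str)
        np.testing.assert_array_equal(d1.deviance_series, d2.deviance_series)

    def test_nonbinary_outcome_rejected(self):
        g = DistrictGraph(("A",), frozenset(), {"A": ""})
        table = _toy_table([0, 1, 2])
        with pytest.raises(ValueError, match="binary"):
            fit(build_design(table, ModelSpec(), g), McmcConfig(iterations=10, burn_in=0))

    def test_structured_draws_sum_to_zero(self, small_scenario):
        _, graph, table, _ = small_scenario
        spec = ModelSpec(structured=True, unstructured=True)
        draws = fit(
            build_design(table, spec, graph),
            McmcConfig(iterations=400, burn_in=100, thin=2, seed=1),
        )
        np.testing.assert_allclose(draws.f_str.sum(axis=1), 0.0, atol=1e-9)

    def test_smooth_draws_centred_over_data(self, small_scenario):
        _, graph, table, _ = small_scenario
        spec = ModelSpec(smooth=(default_full_spec().smooth[0],))
        bundle = build_design(table, spec, graph)
        draws = fit(bundle, McmcConfig(iterations=300, burn_in=100, thin=2, seed=2))
        curve = draws.smooth_coefs["maternal_age"] @ bundle.smooth_bases["maternal_age"].basis.T
        np.testing.assert_allclose(curve.mean(axis=1), 0.0, atol=1e-9)

    def test_forcing_tau2_str_to_zero_collapses_f_str(self, small_scenario):
        _, graph, table, _ = small_scenario
        spec = ModelSpec(structured=True)
        draws = fit(
            build_design(table, spec, graph),
            McmcConfig(iterations=400, burn_in=100, thin=2, seed=3,
                       fix_tau2_str=1e-10),
        )
        assert np.abs(draws.f_str.mean(axis=0)).max() < 0.01


class TestDeviance:
    def test_closed_form_single_observation(self):
        # y=1 with pi=0.5 (eta=0): D = -2 ln 0.5
        assert bernoulli_deviance(np.array([1.0]), np.array([0.0])) == pytest.approx(
            1.3863, abs=1e-4
        )

    def test_perfect_fit_limit(self):
        y = np.array([1.0, 0.0])
        eta = np.array([40.0, -40.0])
        assert bernoulli_deviance(y, eta) < 1e-12

    def test_mean_deviance_dominates_deviance_at_mean(self):
        """Jensen direction of the DIC decomposition (P_D >= 0) across seeds."""
        g = DistrictGraph(("A",), frozenset(), {"A": ""})
        rng = np.random.default_rng(0)
        for seed in range(50):
            y = rng.integers(0, 2, 40)
            table = _toy_table(y.tolist())
            draws = fit(
                build_design(table, ModelSpec(), g),
                McmcConfig(iterations=250, burn_in=50, thin=1, seed=seed),
            )
            dbar = draws.deviance_series.mean()
            dhat = deviance(draws, "mean")
            assert dbar >= dhat - 1e-6

    def test_invalid_mode(self, small_scenario):
        _, graph, table, _ = small_scenario
        draws = fit(
            build_design(table, ModelSpec(), graph),
            McmcConfig(iterations=50, burn_in=10, thin=1, seed=0),
        )
        with pytest.raises(ValueError):
            deviance(draws, "banana")
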