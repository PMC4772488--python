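"""DIC machinery, odds-ratio tables, spatial classification and the builder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geosba.geoadditive_model import (
    McmcConfig,
    ModelSpec,
    PosteriorDraws,
    build_design,
    fit,
    fixed_term,
)
from geosba.selection_summaries import (
    DICReport,
    classify_spatial,
    compute_dic,
    dic_reduction,
    odds_ratio_table,
    percent_reduction,
    spatial_effect_dispersion,
    variance_summary,
)
from geosba.synthetic_data import GeneratorConfig, generate_survey, make_lattice_graph


def _draws_stub(**overrides):
    """Minimal PosteriorDraws for summary-only operations."""
    m = overrides.pop("m", 100)
    base = dict(
        alpha=np.zeros((m, 0)),
        alpha_names=(),
        smooth_coefs={},
        smooth_bases={},
        f_str=np.zeros((m, 1)),
        f_unstr=np.zeros((m, 1)),
        district_ids=("A",),
        tau2={},
        deviance_series=np.zeros(m),
        eta_mean=np.zeros(1),
        y=np.zeros(1),
        config=McmcConfig(iterations=2, burn_in=0, thin=1),
        component_labels=np.zeros(1, int),
    )
    base.update(overrides)
    return PosteriorDraws(**base)


class TestDic:
    def test_identity_and_fields(self):
        rep = DICReport.from_deviances(100.0, 96.0)
        assert rep.p_d == 4.0 and rep.dic == 104.0
        assert rep.dic == 2 * rep.mean_deviance - rep.deviance_at_mean

    def test_equal_deviances_give_zero_complexity(self):
        rep = DICReport.from_deviances(42.0, 42.0)
        assert rep.p_d == 0.0 and rep.dic == 42.0

    def test_negative_p_d_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            DICReport.from_deviances(10.0, 11.0)

    def test_reduction_of_identical_reports_is_zero(self):
        rep = DICReport.from_deviances(50.0, 49.0)
        assert dic_reduction(rep, rep) == 0.0

    def test_effective_parameters_of_identifiable_model(self):
        """An unpenalised two-parameter logistic fit has P_D close to 2."""
        g = make_lattice_graph(1, 1)
        rng = np.random.default_rng(0)
        import pandas as pd
        from collections import Counter

        from geosba.io_types import SurveyTable

        for seed in (1, 2, 3):
            x = rng.choice(["none", "primary"], 400)
            y = rng.binomial(1, np.where(x == "none", 0.4, 0.6))
            df = pd.DataFrame({"outcome": y, "district": "D000", "education": x})
            spec = ModelSpec(
                fixed=(fixed_term("education", levels=("none", "primary")),)
            )
            draws = fit(
                build_design(SurveyTable(df, Counter()), spec, g),
                McmcConfig(iterations=1500, burn_in=300, thin=1, seed=seed),
            )
            assert compute_dic(draws).p_d == pytest.approx(2.0, abs=0.5)


class TestOddsRatioTable:
    def test_zero_coefficient_not_significant(self):
        d = _draws_stub(alpha=np.zeros((100, 2)), alpha_names=("(Intercept)", "x[a]"))
        row = odds_ratio_table(d).iloc[0]
        assert row["or"] == 1.0 and not row["significant"]
        assert (row["lower"], row["upper"]) == (1.0, 1.0)

    def test_tight_draws_near_two(self):
        rng = np.random.default_rng(0)
        coef = rng.normal(np.log(2.0), 1e-4, size=(500, 1))
        d = _draws_stub(m=500, alpha=coef, alpha_names=("x[a]",))
        row = odds_ratio_table(d).iloc[0]
        assert row["or"] == pytest.approx(2.0, rel=1e-3)
        assert row["significant"]

    def test_level_validation(self):
        d = _draws_stub(alpha=np.zeros((10, 1)), alpha_names=("x[a]",), m=10)
        with pytest.raises(ValueError):
            odds_ratio_table(d, level=1.5)

    def test_planted_or_coverage_across_replicates(self):
        """The planted free-delivery OR lies inside the 95% interval in
        at least 90% of seeded replicates (reduced-scale scenario)."""
        hits = 0
        reps = 20
        for seed in range(reps):
            cfg = GeneratorConfig(
                rows=6, cols=5, n_births=4000, seed=100 + seed,
                include_smooths=False,
            )
            graph = make_lattice_graph(cfg.rows, cfg.cols)
            table, truth = generate_survey(cfg, graph)
            spec = ModelSpec(
                fixed=(fixed_term("policy_period"),),
                structured=True,
                unstructured=True,
                primary="policy_period",
            )
            draws = fit(
                build_design(table, spec, graph),
                McmcConfig(iterations=900, burn_in=300, thin=2, seed=seed),
            )
            ors = odds_ratio_table(draws).set_index("term")
            row = ors.loc["policy_period[free_delivery]"]
            if row["lower"] <= np.exp(truth.policy_log_or["free_delivery"]) <= row["upper"]:
                hits += 1
        assert hits >= int(0.9 * reps)


class TestClassifySpatial:
    def test_all_positive_draws_high(self):
        f = np.abs(np.random.default_rng(0).normal(1.0, 0.1, (200, 1)))
        out = classify_spatial(f, ["A"])
        assert out["label"].iloc[0] == "high"

    def test_symmetric_draws_not_significant(self):
        f = np.random.default_rng(0).normal(0.0, 1.0, (500, 1))
        out = classify_spatial(f, ["A"])
        assert out["label"].iloc[0] == "not_significant"

    def test_monotone_in_level(self):
        rng = np.random.default_rng(1)
        f = rng.normal(0.4, 1.0, (400, 30))
        at95 = classify_spatial(f, range(30), 0.95)["label"]
        at99 = classify_spatial(f, range(30), 0.99)["label"]
        for l95, l99 in zip(at95, at99):
            if l99 == "high":
                assert l95 == "high"
            if l99 == "low":
                assert l95 == "low"


class TestVarianceSummary:
    def test_constant_draws(self):
        d = _draws_stub(tau2={"str": np.full(100, 2.5), "unstr": np.full(100, 0.1)})
        out = variance_summary(d).set_index("component")
        assert out.loc["str", "mean"] == 2.5 and out.loc["str", "sd"] == 0.0

    def test_inverse_gamma_moments(self):
        rng = np.random.default_rng(0)
        a, b = 3.0, 2.0
        draws = 1.0 / rng.gamma(a, 1.0 / b, 200_000)
        d = _draws_stub(m=200_000, tau2={"str": draws})
        out = variance_summary(d).set_index("component")
        assert out.loc["str", "mean"] == pytest.approx(b / (a - 1), rel=0.02)
        assert out.loc["str", "sd"] == pytest.approx(
            np.sqrt(b**2 / ((a - 1) ** 2 * (a - 2))), rel=0.05
        )

    def test_dispersion_summary_shape(self):
        rng = np.random.default_rng(0)
        d = _draws_stub(
            f_str=rng.normal(0, 1, (100, 5)),
            f_unstr=rng.normal(0, 0.1, (100, 5)),
            district_ids=tuple("ABCDE"),
        )
        out = spatial_effect_dispersion(d).set_index("component")
        assert out.loc["str", "mean"] > out.loc["unstr", "mean"]


class TestPercentReduction:
    def test_printed_structured_row(self):
        assert percent_reduction(1.52, 0.66) == 56.6

    def test_no_change(self):
        assert percent_reduction(3.3, 3.3) == 0.0

    def test_arithmetic(self):
        assert percent_reduction(2.0, 0.5) == 75.0

    def test_nonpositive_before(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        before=st.floats(0.01, 1e3),
        after=st.floats(0.0, 1e3),
        scale=st.floats(0.01, 1e3),
    )
    def test_scale_invariance(self, before, after, scale):
        assert percent_reduction(before, after) == pytest.approx(
            percent_reduction(before * scale, after * scale), abs=0.1
        )


class TestSequentialBuild:
    def test_structure_and_retention(self, default_sequential):
        result = default_sequential
        assert result.names == ("model1", "model2", "model3", "model4")
        assert len(result.fits) == 4 and len(result.reductions) == 3
        # the pure-noise control is dropped, planted controls retained,
        # and the primary policy factor is never dropped
        assert "ethnicity" in result.dropped
        for kept in ("education", "wealth", "residence", "partner_education"):
            assert kept in result.retained
        assert "policy_period" not in result.dropped
        m4_terms = {n.split("[")[0] for n in result.fits["model4"].alpha_names}
        assert "policy_period" in m4_terms

    def test_spatial_signal_contrast_in_dic(self):
        """Adding the spatial block pays off only when spatial truth exists."""
        reductions = {}
        for label, tau2, offsets in (
            ("null", 0.0, {}),
            ("spatial", 1.0, None),
        ):
            kwargs = dict(rows=4, cols=4, n_births=3000, seed=17,
                          include_smooths=False, tau2_str=tau2, tau2_unstr=0.0)
            if offsets is not None:
                kwargs["band_offsets"] = offsets
            cfg = GeneratorConfig(**kwargs)
            graph = make_lattice_graph(cfg.rows, cfg.cols)
            table, _ = generate_survey(cfg, graph)
            reports = []
            for spec in (ModelSpec(), ModelSpec(structured=True, unstructured=True)):
                draws = fit(
                    build_design(table, spec, graph),
                    McmcConfig(iterations=1200, burn_in=300, thin=2, seed=23),
                )
                reports.append(compute_dic(draws))
            reductions[label] = dic_reduction(*reports)
        assert reductions["null"] < 20
        assert reductions["spatial"] > 200
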