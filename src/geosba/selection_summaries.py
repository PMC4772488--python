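"""Model comparison (DIC), the sequential builder, and posterior summaries.

Covers the inferential reporting layer: the deviance information criterion
and its effective-parameter decomposition, DIC reductions along the
sequential Model 1-4 cascade (null -> +spatial -> +policy -> +controls with
the p < 0.05 retention rule), posterior odds-ratio tables with equal-tailed
credible intervals, per-district classification of the structured spatial
effect at the 95% nominal level, variance-component summaries and the
percent-reduction decomposition of the spatial effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geoadditive_model import (
    McmcConfig,
    ModelSpec,
    PosteriorDraws,
    build_design,
    deviance,
    fit,
)
from .io_types import DistrictGraph, SurveyTable


# --------------------------------------------------------------------------
# DIC

@dataclass(frozen=True)
class DICReport:
    """Fit/complexity decomposition: DIC = D̄(θ) + P_D, P_D = D̄(θ) − D(θ̄)."""

    mean_deviance: float
    deviance_at_mean: float
    p_d: float
    dic: float

    @classmethod
    def from_deviances(cls, mean_deviance: float, deviance_at_mean: float) -> "DICReport":
        p_d = mean_deviance - deviance_at_mean
        if p_d < 0:
            warnings.warn(f"negative effective parameter count p_d = {p_d:.3f}")
        return cls(mean_deviance, deviance_at_mean, p_d, mean_deviance + p_d)


def compute_dic(draws: PosteriorDraws) -> DICReport:
    """DIC of a fitted model from its stored deviance series."""
    if draws.n_draws == 0:
        raise RuntimeError("no retained draws")
    dbar = float(np.mean(deviance(draws, "per-iteration")))
    dhat = float(deviance(draws, "mean"))
    return DICReport.from_deviances(dbar, dhat)


def dic_reduction(previous, current) -> float:
    """previous DIC minus current DIC (positive = the new model fits better).

    Accepts :class:`DICReport` objects or raw DIC values.
    """
    prev = previous.dic if isinstance(previous, DICReport) else float(previous)
    cur = current.dic if isinstance(current, DICReport) else float(current)
    return prev - cur


# --------------------------------------------------------------------------
# posterior summaries

def odds_ratio_table(
    draws: PosteriorDraws, level: float = 0.95, point: str = "mean"
) -> pd.DataFrame:
    """Posterior odds ratios of the fixed effects with credible intervals.

    OR = exp(posterior mean coefficient) (``point="median"`` for the
    exponentiated median); bounds are exponentiated equal-tailed quantiles;
    a term is flagged significant when its interval excludes 1.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if draws.alpha.shape[1] == 0:
        raise RuntimeError("no fixed-effect draws")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for j, name in enumerate(draws.alpha_names):
        if name == "(Intercept)":
            continue
        coef = draws.alpha[:, j]
        centre = np.mean(coef) if point == "mean" else np.median(coef)
        lo, hi = np.quantile(coef, [lo_q, hi_q])
        rows.append(
            {
                "term": name,
                "or": float(np.exp(centre)),
                "lower": float(np.exp(lo)),
                "upper": float(np.exp(hi)),
                "significant": bool(np.exp(lo) > 1.0 or np.exp(hi) < 1.0),
            }
        )
    return pd.DataFrame(rows)


def classify_spatial(
    f_draws: np.ndarray,
    district_ids,
    level: float = 0.95,
) -> pd.DataFrame:
    """Label each district low / high / not_significant at the nominal level.

    ``high`` when the equal-tailed interval lies entirely above zero, ``low``
    entirely below, else ``not_significant``.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo, hi = np.quantile(f_draws, [lo_q, hi_q], axis=0)
    mean = f_draws.mean(axis=0)
    label = np.where(hi < 0, "low", np.where(lo > 0, "high", "not_significant"))
    return pd.DataFrame(
        {
            "district": list(district_ids),
            "mean": mean,
            "lower": lo,
            "upper": hi,
            "label": label,
        }
    )


def variance_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean [SD] of the spatial variance components tau2."""
    rows = []
    for comp in ("str", "unstr"):
        if comp in draws.tau2:
            t = draws.tau2[comp]
            rows.append(
                {"component": comp, "mean": float(t.mean()), "sd": float(t.std(ddof=0))}
            )
    if not rows:
        raise RuntimeError("no spatial variance component draws")
    return pd.DataFrame(rows)


def spatial_effect_dispersion(draws: PosteriorDraws) -> pd.DataFrame:
    """Alternative scalar summary: per-draw SD of the district effects.

    Posterior mean [SD] of the cross-district standard deviation of f_str
    and f_unstr; reported alongside the variance components because printed
    "posterior mean spatial effect" summaries are ambiguous between the two.
    """
    rows = []
    for name, f in (("str", draws.f_str), ("unstr", draws.f_unstr)):
        sd_per_draw = f.std(axis=1, ddof=0)
        rows.append(
            {
                "component": name,
                "mean": float(sd_per_draw.mean()),
                "sd": float(sd_per_draw.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SpatialSummary:
    """Per-district posterior summaries plus variance components."""

    structured: pd.DataFrame       # classify_spatial frame for f_str
    unstructured: pd.DataFrame     # same for f_unstr
    variance: pd.DataFrame         # variance_summary frame
    dispersion: pd.DataFrame       # spatial_effect_dispersion frame
    level: float


def make_spatial_summary(draws: PosteriorDraws, level: float = 0.95) -> SpatialSummary:
    return SpatialSummary(
        structured=classify_spatial(draws.f_str, draws.district_ids, level),
        unstructured=classify_spatial(draws.f_unstr, draws.district_ids, level),
        variance=variance_summary(draws),
        dispersion=spatial_effect_dispersion(draws),
        level=level,
    )


def percent_reduction(before: float, after: float) -> float:
    """100 * (before - after) / before, to one decimal."""
    if before <= 0:
        raise ValueError("'before' summary must be positive")
    return round(100.0 * (before - after) / before, 1)


# --------------------------------------------------------------------------
# sequential model building

@dataclass
class SequentialResult:
    """The four-model cascade with DIC bookkeeping and retention decisions."""

    names: tuple[str, ...]
    fits: dict[str, PosteriorDraws]
    dic_reports: dict[str, DICReport]
    reductions: tuple[float, ...]        # per-step previous - current DIC
    retained: tuple[str, ...]            # control fixed terms kept in Model 4
    dropped: dict[str, str]              # term -> reason


def sequential_build(
    table: SurveyTable,
    graph: DistrictGraph,
    full_spec: ModelSpec,
    mcmc: McmcConfig,
) -> SequentialResult:
    """Fit the Model 1-4 cascade and apply the covariate-retention rule.

    Model 1 is the null (intercept only), Model 2 adds the structured and
    unstructured spatial effects, Model 3 adds the primary policy factor,
    and Model 4 adds the controls (remaining fixed terms and all smooths).
    In Model 4, control fixed effects whose 95% equal-tailed credible
    interval includes the null odds ratio of 1 for every non-reference level
    are dropped and the model refitted once; the primary factor is always
    retained. Each step's DIC report and reduction is recorded.
    """
    if full_spec.primary is None:
        raise ValueError("full_spec must declare the primary fixed term")
    primary = next(t for t in full_spec.fixed if t.name == full_spec.primary)

    specs = {
        "model1": ModelSpec(),
        "model2": ModelSpec(structured=full_spec.structured,
                            unstructured=full_spec.unstructured),
        "model3": ModelSpec(
            fixed=(primary,),
            structured=full_spec.structured,
            unstructured=full_spec.unstructured,
            primary=full_spec.primary,
        ),
        "model4": full_spec,
    }

    fits: dict[str, PosteriorDraws] = {}
    reports: dict[str, DICReport] = {}
    dropped: dict[str, str] = {}
    for step, (name, spec) in enumerate(specs.items()):
        cfg = replace(mcmc, seed=mcmc.seed + step)
        try:
            bundle = build_design(table, spec, graph)
            draws = fit(bundle, cfg)
        except Exception as exc:
            raise RuntimeError(f"sequential build failed at {name}") from exc
        if name == "model4":
            ors = odds_ratio_table(draws)
            to_drop = set()
            for term in spec.fixed:
                if term.name == full_spec.primary:
                    continue
                level_rows = ors[ors["term"].str.startswith(f"{term.name}[")]
                if not level_rows["significant"].any():
                    to_drop.add(term.name)
                    dropped[term.name] = "95% credible interval includes OR 1 for every level"
            if to_drop:
                spec = spec.drop_fixed(to_drop)
                specs["model4"] = spec
                bundle = build_design(table, spec, graph)
                draws = fit(bundle, cfg)
        fits[name] = draws
        reports[name] = compute_dic(draws)

    names = tuple(specs)
    reductions = tuple(
        dic_reduction(reports[a], reports[b]) for a, b in zip(names, names[1:])
    )
    retained = tuple(t.name for t in specs["model4"].fixed if t.name != full_spec.primary)
    return SequentialResult(names, fits, reports, reductions, retained, dropped)
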