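"""Bayesian geoadditive logistic model for district-level skilled birth care.

The linear predictor combines fixed categorical effects, penalised-spline
smooths of the continuous covariates, a spatially structured district effect
under an intrinsic CAR (Gaussian Markov random field) prior on the district
adjacency graph, and an exchangeable unstructured district effect:

    eta_ij = alpha' lambda_ij + sum_k f_k(x_ijk) + f_str(S_j) + f_unstr(S_j)
    y_ij | eta_ij ~ Bernoulli(logit^-1(eta_ij))

Priors: diffuse Gaussians on fixed effects; random-walk (difference-penalty)
Gaussian priors on spline coefficients with variance tau2_k; ICAR prior with
precision K / tau2_str (K the graph Laplacian) on the structured effect,
identified by a per-component sum-to-zero constraint; iid N(0, tau2_unstr)
unstructured effects; inverse-gamma(a, b) hyperpriors on all variances.

Posterior sampling is by Polya-Gamma auxiliary-variable Gibbs: given
omega_ij ~ PG(1, eta_ij), every coefficient block has a Gaussian full
conditional, so the chain is a sequence of exact conditional draws. The
per-iteration deviance D = -2 log p(y | theta) is recorded for DIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ._polya_gamma import random_polya_gamma
from .io_types import CATEGORY_LEVELS, DistrictGraph, SurveyTable, UnknownDistrictError


class DegenerateCovariateError(ValueError):
    """Covariate has too few distinct values to support a spline basis."""


# --------------------------------------------------------------------------
# spline basis

@dataclass(frozen=True)
class SplineBasis:
    """A B-spline design with an equidistant knot grid and difference penalty.

    The penalty D'D (D the ``penalty_order``-th difference operator on the
    coefficients) is the Bayesian random-walk prior precision; its null space
    has dimension equal to the penalty order.
    """

    knots: np.ndarray            # full (augmented) knot vector
    degree: int
    penalty_order: int
    basis: np.ndarray            # n x m design matrix
    penalty: np.ndarray          # m x m = D'D
    x_range: tuple[float, float]

    @property
    def n_coef(self) -> int:
        return self.basis.shape[1]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at new points (clipped to the training range)."""
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        return BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()


def build_spline_basis(
    x: np.ndarray,
    n_knots: int = 20,
    degree: int = 3,
    penalty_order: int = 2,
) -> SplineBasis:
    """Build a P-spline basis on ``[min x, max x]`` with equidistant knots.

    ``n_knots`` counts the knot grid over the data range; the basis has
    ``n_knots + degree - 1`` functions and satisfies partition of unity on
    the closed data range.
    """
    x = np.asarray(x, dtype=float)
    if n_knots < 4:
        raise ValueError("n_knots must be >= 4")
    uniq = np.unique(x)
    if uniq.size < degree + 2:
        raise DegenerateCovariateError(
            f"need >= {degree + 2} distinct values, got {uniq.size}"
        )
    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, n_knots)
    step = grid[1] - grid[0]
    knots = np.concatenate(
        [lo - step * np.arange(degree, 0, -1), grid, hi + step * np.arange(1, degree + 1)]
    )
    basis = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    m = n_knots + degree - 1
    d = np.diff(np.eye(m), penalty_order, axis=0)
    return SplineBasis(knots, degree, penalty_order, basis, d.T @ d, (lo, hi))


# --------------------------------------------------------------------------
# graph precision

def graph_precision(graph: DistrictGraph) -> np.ndarray:
    """Graph Laplacian K (degree on the diagonal, -1 for neighbours).

    K is the ICAR prior precision up to the scale 1/tau2_str; it is PSD with
    one zero eigenvalue per connected component (zero rows for isolated
    districts).
    """
    idx = graph.index_of()
    s = graph.n_districts
    k = np.zeros((s, s))
    for a, b in graph.edges:
        i, j = idx[a], idx[b]
        k[i, j] -= 1.0
        k[j, i] -= 1.0
        k[i, i] += 1.0
        k[j, j] += 1.0
    return k


# --------------------------------------------------------------------------
# model specification and design

#: Table-3-style reference (base) levels for the categorical covariates
DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "education": "none",
    "religion": "christian",
    "ethnicity": "akan",
    "partner_education": "none_dk",
    "wealth": "poorest",
    "residence": "urban",
    "policy_period": "cash_and_carry",
}

POLICY_LEVELS = ("cash_and_carry", "free_antenatal", "free_delivery", "nhis")


@dataclass(frozen=True)
class FixedTerm:
    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(f"reference {self.reference!r} not a level of {self.name}")


@dataclass(frozen=True)
class SmoothTerm:
    name: str
    n_knots: int = 20
    degree: int = 3
    penalty_order: int = 2


@dataclass(frozen=True)
class ModelSpec:
    """Which blocks enter the predictor (expresses the sequential Models 1-4)."""

    fixed: tuple[FixedTerm, ...] = ()
    smooth: tuple[SmoothTerm, ...] = ()
    structured: bool = False
    unstructured: bool = False
    primary: str | None = None   # fixed term always retained by the builder
    #: drop only for degenerate test models (e.g. pure random-effect toys)
    intercept: bool = True

    def __post_init__(self) -> None:
        fixed_names = [t.name for t in self.fixed]
        smooth_names = [t.name for t in self.smooth]
        overlap = set(fixed_names) & set(smooth_names)
        if overlap:
            raise ValueError(f"covariate(s) in both fixed and smooth blocks: {overlap}")
        if len(set(fixed_names)) != len(fixed_names):
            raise ValueError("duplicate fixed terms")
        if self.primary is not None and self.primary not in fixed_names:
            raise ValueError(f"primary term {self.primary!r} not among fixed terms")

    def drop_fixed(self, names: set[str]) -> "ModelSpec":
        return replace(self, fixed=tuple(t for t in self.fixed if t.name not in names))


def fixed_term(name: str, reference: str | None = None,
               levels: Sequence[str] | None = None) -> FixedTerm:
    """Convenience constructor using the catalogued levels and base levels."""
    if levels is None:
        levels = POLICY_LEVELS if name == "policy_period" else CATEGORY_LEVELS[name]
    if reference is None:
        reference = DEFAULT_REFERENCE_LEVELS[name]
    return FixedTerm(name, tuple(levels), reference)


def default_full_spec(n_knots: int = 20) -> ModelSpec:
    """The full model: policy (primary) + controls + smooths + both spatial blocks."""
    return ModelSpec(
        fixed=(
            fixed_term("policy_period"),
            fixed_term("education"),
            fixed_term("religion"),
            fixed_term("ethnicity"),
            fixed_term("partner_education"),
            fixed_term("wealth"),
            fixed_term("residence"),
        ),
        smooth=tuple(
            SmoothTerm(n, n_knots=n_knots)
            for n in ("maternal_age", "parity", "anc_visits", "distance_km")
        ),
        structured=True,
        unstructured=True,
        primary="policy_period",
    )


@dataclass
class DesignBundle:
    """Assembled design structures for one model fit."""

    y: np.ndarray
    x_fixed: np.ndarray                  # n x d, first column the intercept
    fixed_names: tuple[str, ...]         # "(Intercept)", "var[level]", ...
    smooth_bases: dict[str, SplineBasis]
    smooth_x: dict[str, np.ndarray]
    district_index: np.ndarray           # n, positions into graph.district_ids
    graph: DistrictGraph
    precision: np.ndarray                # Laplacian K
    spec: ModelSpec
    component_labels: np.ndarray         # per district, component id (-1 isolated)

    @property
    def n_obs(self) -> int:
        return self.y.size

    def assemble_eta(
        self,
        alpha_by_name: Mapping[str, float],
        smooth_functions: Mapping[str, Callable[[np.ndarray], np.ndarray]] | None = None,
        f_str: np.ndarray | None = None,
        f_unstr: np.ndarray | None = None,
    ) -> np.ndarray:
        """Evaluate the predictor for given effects through the design structures.

        Independent route for checking that dummy coding and district
        alignment reproduce a generator's predictor exactly.
        """
        coef = np.array([alpha_by_name.get(n, 0.0) for n in self.fixed_names])
        eta = self.x_fixed @ coef
        if smooth_functions:
            for name, fn in smooth_functions.items():
                eta = eta + fn(self.smooth_x[name])
        if f_str is not None:
            eta = eta + np.asarray(f_str)[self.district_index]
        if f_unstr is not None:
            eta = eta + np.asarray(f_unstr)[self.district_index]
        return eta


def build_design(table: SurveyTable, spec: ModelSpec, graph: DistrictGraph) -> DesignBundle:
    """Dummy-code fixed terms, build spline bases, and align districts to the graph."""
    df = table.df
    n = len(df)
    cols = [np.ones(n)] if spec.intercept else []
    names = ["(Intercept)"] if spec.intercept else []
    for term in spec.fixed:
        if term.name not in df.columns:
            raise KeyError(f"column {term.name!r} absent from survey table")
        values = df[term.name].astype(str)
        unknown = set(values.unique()) - set(term.levels)
        if unknown:
            raise ValueError(f"{term.name}: unknown level(s) {unknown}")
        for level in term.levels:
            if level == term.reference:
                continue
            col = (values == level).to_numpy(dtype=float)
            if col.sum() == 0:
                warnings.warn(f"{term.name}[{level}]: level absent from data")
            cols.append(col)
            names.append(f"{term.name}[{level}]")
    x_fixed = np.column_stack(cols) if cols else np.zeros((n, 0))

    smooth_bases, smooth_x = {}, {}
    for term in spec.smooth:
        x = df[term.name].to_numpy(dtype=float)
        smooth_bases[term.name] = build_spline_basis(
            x, term.n_knots, term.degree, term.penalty_order
        )
        smooth_x[term.name] = x

    idx = graph.index_of()
    try:
        district_index = df["district"].map(idx).to_numpy()
    except Exception as exc:  # pragma: no cover
        raise UnknownDistrictError(str(exc)) from exc
    if pd.isna(district_index).any():
        bad = df.loc[pd.isna(df["district"].map(idx)), "district"].unique()
        raise UnknownDistrictError(f"district(s) not in graph: {list(bad)[:5]}")
    district_index = district_index.astype(int)

    comp_labels = np.full(graph.n_districts, -1, dtype=int)
    isolated = set(graph.isolated_districts())
    cid = 0
    for comp in graph.components():
        comp = comp - isolated
        if not comp:
            continue
        for d in comp:
            comp_labels[idx[d]] = cid
        cid += 1

    return DesignBundle(
        y=df["outcome"].to_numpy(dtype=float),
        x_fixed=x_fixed,
        fixed_names=tuple(names),
        smooth_bases=smooth_bases,
        smooth_x=smooth_x,
        district_index=district_index,
        graph=graph,
        precision=graph_precision(graph),
        spec=spec,
        component_labels=comp_labels,
    )


# --------------------------------------------------------------------------
# MCMC

@dataclass(frozen=True)
class McmcConfig:
    """Chain length and hyperprior settings.

    Defaults follow common BayesX-style conventions: inverse-gamma(0.001,
    0.001) on every variance component, N(0, 1e6) on fixed effects, 12,000
    iterations with 2,000 burn-in thinned by 10.
    """

    iterations: int = 12000
    burn_in: int = 2000
    thin: int = 10
    seed: int = 0
    hyper_a: float = 0.001
    hyper_b: float = 0.001
    fixed_prior_var: float = 1e6
    #: pin a spatial variance component instead of sampling it (prior-limit checks)
    fix_tau2_str: float | None = None
    fix_tau2_unstr: float | None = None

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of every model block plus the deviance series."""

    alpha: np.ndarray                       # M x d
    alpha_names: tuple[str, ...]
    smooth_coefs: dict[str, np.ndarray]     # name -> M x m (centred contributions)
    smooth_bases: dict[str, SplineBasis]
    f_str: np.ndarray                       # M x S
    f_unstr: np.ndarray                     # M x S
    district_ids: tuple[str, ...]
    tau2: dict[str, np.ndarray]             # "str", "unstr", "smooth:<name>" -> M
    deviance_series: np.ndarray             # M
    eta_mean: np.ndarray                    # n, posterior mean linear predictor
    y: np.ndarray
    config: McmcConfig
    component_labels: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.deviance_series.size

    def fixed_coef_draws(self, name: str) -> np.ndarray:
        return self.alpha[:, self.alpha_names.index(name)]

    def smooth_curve(self, name: str, grid: np.ndarray) -> np.ndarray:
        """Draws of the centred smooth evaluated on ``grid`` (M x len(grid))."""
        b = self.smooth_bases[name].evaluate(grid)
        return self.smooth_coefs[name] @ b.T

    def save(self, directory) -> None:
        """Serialise draws as CSV columns plus a JSON manifest."""
        import json
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.alpha, columns=list(self.alpha_names)).to_csv(
            d / "alpha.csv", index=False
        )
        pd.DataFrame(self.f_str, columns=list(self.district_ids)).to_csv(
            d / "f_str.csv", index=False
        )
        pd.DataFrame(self.f_unstr, columns=list(self.district_ids)).to_csv(
            d / "f_unstr.csv", index=False
        )
        pd.DataFrame(self.tau2).to_csv(d / "tau2.csv", index=False)
        pd.DataFrame(
            {"deviance": self.deviance_series}
        ).to_csv(d / "deviance.csv", index=False)
        for name, coefs in self.smooth_coefs.items():
            pd.DataFrame(coefs).to_csv(d / f"smooth_{name}.csv", index=False)
        manifest = {
            "n_draws": int(self.n_draws),
            "config": {
                "iterations": self.config.iterations,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "seed": self.config.seed,
                "hyper_a": self.config.hyper_a,
                "hyper_b": self.config.hyper_b,
            },
            "district_ids": list(self.district_ids),
            "alpha_names": list(self.alpha_names),
            "smooths": list(self.smooth_coefs),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def bernoulli_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """D = -2 log p(y | eta) for the Bernoulli-logit likelihood."""
    return float(-2.0 * np.sum(y * eta - np.logaddexp(0.0, eta)))


def _draw_gaussian_block(
    q: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(Q^-1 b, Q^-1) via Cholesky."""
    c, low = cho_factor(q, lower=True)
    mean = cho_solve((c, low), b)
    z = rng.standard_normal(b.size)
    return mean + solve_triangular(c, z, lower=True, trans="T")


def fit(bundle: DesignBundle, mcmc: McmcConfig) -> PosteriorDraws:
    """Run the Polya-Gamma Gibbs sampler for the specified geoadditive model.

    Block updates per iteration: omega | eta; fixed effects; each smooth
    (then recentred to mean zero over the data, the offset absorbed into the
    intercept); structured effects (recentred per graph component, the shift
    absorbed into the intercept when the graph has a single component);
    unstructured effects; all variance components. Deviance is recorded each
    retained iteration. Reproducible from ``mcmc.seed``.
    """
    y = bundle.y
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    rng = np.random.default_rng(mcmc.seed)
    n = y.size
    spec = bundle.spec
    kappa = y - 0.5

    xf = bundle.x_fixed
    d_fix = xf.shape[1]
    prior_prec_fixed = np.eye(d_fix) / mcmc.fixed_prior_var
    has_intercept = spec.intercept and d_fix > 0

    smooth_names = list(bundle.smooth_bases)
    bases = {nm: bundle.smooth_bases[nm].basis for nm in smooth_names}
    penalties = {nm: bundle.smooth_bases[nm].penalty for nm in smooth_names}
    pen_rank = {
        nm: bundle.smooth_bases[nm].n_coef - bundle.smooth_bases[nm].penalty_order
        for nm in smooth_names
    }

    s = bundle.graph.n_districts
    di = bundle.district_index
    k_mat = bundle.precision
    comp = bundle.component_labels
    active = comp >= 0                     # non-isolated districts
    n_comp = int(comp.max()) + 1 if active.any() else 0
    rank_k = int(active.sum()) - n_comp
    single_component = n_comp == 1 and active.all()
    if spec.structured and (~active).any():
        warnings.warn(
            f"{int((~active).sum())} isolated district(s): structured effect pinned to 0"
        )

    # state
    beta = np.zeros(d_fix)
    gamma = {nm: np.zeros(bases[nm].shape[1]) for nm in smooth_names}
    eta_smooth = {nm: np.zeros(n) for nm in smooth_names}
    f_str = np.zeros(s)
    f_unstr = np.zeros(s)
    tau2_s = {nm: 0.1 for nm in smooth_names}
    tau2_str = mcmc.fix_tau2_str if mcmc.fix_tau2_str is not None else 0.1
    tau2_unstr = mcmc.fix_tau2_unstr if mcmc.fix_tau2_unstr is not None else 0.1
    eta_fix = xf @ beta
    eta = eta_fix.copy()

    m_draws = mcmc.n_draws
    out_alpha = np.empty((m_draws, d_fix))
    out_smooth = {nm: np.empty((m_draws, bases[nm].shape[1])) for nm in smooth_names}
    out_fstr = np.empty((m_draws, s))
    out_funstr = np.empty((m_draws, s))
    out_tau2 = {}
    if spec.structured:
        out_tau2["str"] = np.empty(m_draws)
    if spec.unstructured:
        out_tau2["unstr"] = np.empty(m_draws)
    for nm in smooth_names:
        out_tau2[f"smooth:{nm}"] = np.empty(m_draws)
    out_dev = np.empty(m_draws)
    eta_sum = np.zeros(n)

    a0, b0 = mcmc.hyper_a, mcmc.hyper_b
    keep = 0
    for it in range(mcmc.iterations):
        omega = random_polya_gamma(eta, rng)

        def recompute_eta():
            e = eta_fix
            for v in eta_smooth.values():
                e = e + v
            if spec.structured or spec.unstructured:
                e = e + (f_str + f_unstr)[di]
            return e

        # fixed effects
        if d_fix:
            r = kappa - omega * (eta - eta_fix)
            q = (xf * omega[:, None]).T @ xf + prior_prec_fixed
            beta = _draw_gaussian_block(q, xf.T @ r, rng)
            eta_fix = xf @ beta
            eta = recompute_eta()

        # smooths
        for nm in smooth_names:
            bmat = bases[nm]
            r = kappa - omega * (eta - eta_smooth[nm])
            q = (bmat * omega[:, None]).T @ bmat + penalties[nm] / tau2_s[nm]
            # difference penalties leave polynomial null space; tiny ridge for safety
            q[np.diag_indices_from(q)] += 1e-10
            g = _draw_gaussian_block(q, bmat.T @ r, rng)
            contrib = bmat @ g
            shift = contrib.mean()
            # partition of unity: a uniform coefficient shift moves the whole
            # curve, so the centred smooth is B(g - shift); intercept absorbs it
            g = g - shift
            contrib = contrib - shift
            if has_intercept:
                beta[0] += shift
                eta_fix = xf @ beta
            eta_smooth[nm] = contrib
            gamma[nm] = g
            eta = recompute_eta()
            # variance component (difference penalty annihilates the shift)
            quad = float(g @ penalties[nm] @ g)
            tau2_s[nm] = 1.0 / rng.gamma(a0 + pen_rank[nm] / 2.0, 1.0 / (b0 + quad / 2.0))

        # structured spatial effects
        if spec.structured and active.any():
            eta_str = f_str[di]
            r = kappa - omega * (eta - eta_str)
            w_sum = np.bincount(di, weights=omega, minlength=s)
            b_vec = np.bincount(di, weights=r, minlength=s)
            ai = np.flatnonzero(active)
            q = k_mat[np.ix_(ai, ai)] / tau2_str
            q[np.diag_indices_from(q)] += w_sum[ai] + 1e-10
            draw = _draw_gaussian_block(q, b_vec[ai], rng)
            f_str = np.zeros(s)
            f_str[ai] = draw
            # per-component sum-to-zero; with one component the shift moves
            # into the intercept exactly (a null direction of the ICAR prior)
            for c in range(n_comp):
                mask = comp == c
                m_c = f_str[mask].mean()
                f_str[mask] -= m_c
                if single_component and has_intercept:
                    beta[0] += m_c
            eta_fix = xf @ beta
            eta = recompute_eta()
            if mcmc.fix_tau2_str is None:
                quad = float(f_str @ k_mat @ f_str)
                tau2_str = 1.0 / rng.gamma(a0 + rank_k / 2.0, 1.0 / (b0 + quad / 2.0))

        # unstructured spatial effects (diagonal conditional)
        if spec.unstructured:
            eta_un = f_unstr[di]
            r = kappa - omega * (eta - eta_un)
            w_sum = np.bincount(di, weights=omega, minlength=s)
            b_vec = np.bincount(di, weights=r, minlength=s)
            prec = w_sum + 1.0 / tau2_unstr
            mean = b_vec / prec
            f_unstr = mean + rng.standard_normal(s) / np.sqrt(prec)
            eta = eta + (f_unstr[di] - eta_un)
            if mcmc.fix_tau2_unstr is None:
                quad = float(f_unstr @ f_unstr)
                tau2_unstr = 1.0 / rng.gamma(a0 + s / 2.0, 1.0 / (b0 + quad / 2.0))

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and keep < m_draws:
            out_alpha[keep] = beta
            for nm in smooth_names:
                out_smooth[nm][keep] = gamma[nm]
                out_tau2[f"smooth:{nm}"][keep] = tau2_s[nm]
            out_fstr[keep] = f_str
            out_funstr[keep] = f_unstr
            if spec.structured:
                out_tau2["str"][keep] = tau2_str
            if spec.unstructured:
                out_tau2["unstr"][keep] = tau2_unstr
            out_dev[keep] = bernoulli_deviance(y, eta)
            eta_sum += eta
            keep += 1

    draws = PosteriorDraws(
        alpha=out_alpha[:keep],
        alpha_names=bundle.fixed_names,
        smooth_coefs={nm: out_smooth[nm][:keep] for nm in smooth_names},
        smooth_bases=bundle.smooth_bases,
        f_str=out_fstr[:keep],
        f_unstr=out_funstr[:keep],
        district_ids=bundle.graph.district_ids,
        tau2={kk: vv[:keep] for kk, vv in out_tau2.items()},
        deviance_series=out_dev[:keep],
        eta_mean=eta_sum / max(keep, 1),
        y=y,
        config=mcmc,
        component_labels=comp,
    )
    big = np.abs(draws.alpha.mean(axis=0)) > 15
    if big.any():
        warnings.warn(
            "possible separation / degenerate block: very large posterior "
            f"mean coefficient(s) for {[bundle.fixed_names[i] for i in np.flatnonzero(big)]}"
        )
    return draws


def deviance(draws: PosteriorDraws, at: str = "per-iteration"):
    """Deviance series (``"per-iteration"``) or D at the posterior mean (``"mean"``).

    The predictor is linear in every parameter block, so evaluating D at the
    posterior mean of the parameters equals evaluating it at the posterior
    mean predictor.
    """
    if draws.n_draws == 0:
        raise RuntimeError("no retained draws")
    if at == "per-iteration":
        return draws.deviance_series
    if at == "mean":
        return bernoulli_deviance(draws.y, draws.eta_mean)
    raise ValueError(f"at must be 'mean' or 'per-iteration', got {at!r}")
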