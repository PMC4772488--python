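"""Synthetic GDHS-like survey data with known ground truth.

Generates district lattices, intrinsic-CAR spatial effects, birth records
whose outcome is simulated forward through the geoadditive predictor, and
random road networks for the accessibility stage. Every generated quantity
is recorded in a :class:`TruthBundle` so downstream estimates can be tested
against truth.

The default scenario mirrors the scale of the pooled 1993-2008 Ghanaian
birth-history file: 110 districts on a 10 x 11 lattice, ~12,200 births,
policy-era shares (0.41, 0.38, 0.13, 0.07), planted policy odds ratios
(1.17, 1.67, 1.65) versus the fee-paying baseline, and a pronounced
north-south gradient in the structured spatial effect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_types import (
    ANALYSIS_WINDOW,
    FREE_ANTENATAL_START,
    FREE_DELIVERY_START_DEPRIVED,
    FREE_DELIVERY_START_NATIONAL,
    NHIS_START,
    DistrictGraph,
    PolicyPeriod,
    SurveyTable,
)


# --------------------------------------------------------------------------
# lattice district map

def make_lattice_graph(rows: int, cols: int) -> DistrictGraph:
    """Rook-adjacency lattice of districts with row-band regions.

    Regions are assigned by row bands (top ~30% of rows = "north", bottom
    ~30% = "south", middle = "central") so that north-south spatial patterns
    can be planted and recovered.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    ids = [f"D{r * cols + c:03d}" for r in range(rows) for c in range(cols)]
    edges = set()
    for r in range(rows):
        for c in range(cols):
            i = ids[r * cols + c]
            if c + 1 < cols:
                edges.add(tuple(sorted((i, ids[r * cols + c + 1]))))
            if r + 1 < rows:
                edges.add(tuple(sorted((i, ids[(r + 1) * cols + c]))))
    n_north = max(1, round(rows * 0.3))
    n_south = max(0, min(rows - n_north, round(rows * 0.3)))
    region_of = {}
    for r in range(rows):
        if r < n_north:
            band = "north"
        elif r >= rows - n_south:
            band = "south"
        else:
            band = "central"
        for c in range(cols):
            region_of[ids[r * cols + c]] = band
    return DistrictGraph(tuple(ids), frozenset(edges), region_of)


# --------------------------------------------------------------------------
# intrinsic CAR draws

def sample_car_effects(
    graph: DistrictGraph, tau2: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw from the intrinsic CAR density with precision K / tau2.

    Sampled by eigendecomposition of the graph Laplacian K, drawing only the
    directions with nonzero eigenvalue (variance tau2 / lambda_i), so the
    result sums to zero within each connected component and isolated
    districts get exactly zero.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be > 0")
    if graph.n_districts == 0:
        raise ValueError("empty graph")
    from .geoadditive_model import graph_precision

    k = graph_precision(graph)
    evals, evecs = np.linalg.eigh(k)
    pos = evals > 1e-9
    z = rng.standard_normal(int(pos.sum()))
    return evecs[:, pos] @ (z * np.sqrt(tau2 / evals[pos]))


# --------------------------------------------------------------------------
# truth bundle and generator configuration

@dataclass
class TruthBundle:
    """Ground truth behind one synthetic survey."""

    intercept: float
    alpha: dict[str, float]                  # "var[level]" -> log-odds
    policy_log_or: dict[str, float]          # era -> log OR vs cash_and_carry
    smooth_functions: dict[str, Callable[[np.ndarray], np.ndarray]]  # centred
    f_str: np.ndarray                        # per district, sums to 0 per component
    f_unstr: np.ndarray                      # per district, mean 0
    tau2_str: float
    tau2_unstr: float
    district_ids: tuple[str, ...]
    #: the simulated per-record predictor, in record order (not serialised)
    eta: np.ndarray | None = None

    def fixed_effects_by_name(self) -> dict[str, float]:
        """True fixed effects keyed by design column name, incl. policy terms."""
        out = {"(Intercept)": self.intercept, **self.alpha}
        for era, coef in self.policy_log_or.items():
            out[f"policy_period[{era}]"] = coef
        return out

    def to_json(self, path, grid_points: int = 101) -> None:
        """Serialise truth; smooths are stored as curves on covariate grids."""
        grids = {
            "maternal_age": np.linspace(15, 49, grid_points),
            "parity": np.linspace(1, 15, grid_points),
            "anc_visits": np.linspace(0, 20, grid_points),
            "distance_km": np.linspace(0, 60, grid_points),
        }
        payload = {
            "intercept": self.intercept,
            "alpha": self.alpha,
            "policy_log_or": self.policy_log_or,
            "tau2_str": self.tau2_str,
            "tau2_unstr": self.tau2_unstr,
            "district_ids": list(self.district_ids),
            "f_str": self.f_str.tolist(),
            "f_unstr": self.f_unstr.tolist(),
            "smooths": {
                name: {"x": g.tolist(), "f": self.smooth_functions[name](g).tolist()}
                for name, g in grids.items()
                if name in self.smooth_functions
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _default_alpha() -> dict[str, float]:
    # log odds, magnitudes in line with the published adjusted odds ratios
    return {
        "education[primary]": math.log(1.15),
        "education[secondary+]": math.log(1.66),
        "religion[muslim]": 0.0,
        "religion[other]": math.log(0.56),
        "partner_education[primary]": math.log(1.31),
        "partner_education[secondary+]": math.log(1.53),
        "wealth[poor]": math.log(1.19),
        "wealth[middle]": math.log(1.24),
        "wealth[rich]": math.log(1.42),
        "wealth[richest]": math.log(2.15),
        "residence[rural]": math.log(0.33),
        # ethnicity carries no true effect (it drops out of the final model)
        "ethnicity[ga_dangbe]": 0.0,
        "ethnicity[ewe_guan]": 0.0,
        "ethnicity[mole_dagbane]": 0.0,
        "ethnicity[grussi_gruma_hausa]": 0.0,
        "ethnicity[other]": 0.0,
    }


def _default_category_probs() -> dict[str, dict[str, float]]:
    # marginal mixes matching the pooled survey composition
    return {
        "education": {"none": 0.436, "primary": 0.272, "secondary+": 0.292},
        "religion": {"christian": 0.655, "muslim": 0.174, "other": 0.171},
        "ethnicity": {
            "akan": 0.416,
            "ga_dangbe": 0.060,
            "ewe_guan": 0.141,
            "mole_dagbane": 0.200,
            "grussi_gruma_hausa": 0.116,
            "other": 0.067,
        },
        "partner_education": {"none_dk": 0.410, "primary": 0.151, "secondary+": 0.439},
        "wealth": {
            "poorest": 0.274,
            "poor": 0.217,
            "middle": 0.177,
            "rich": 0.174,
            "richest": 0.158,
        },
        "residence": {"urban": 0.273, "rural": 0.727},
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    Defaults are the default scenario: 110 lattice districts, ~12,200
    births, era shares from the pooled table denominators, planted policy
    odds ratios 1.17 / 1.67 / 1.65, tau2_str = 1, tau2_unstr = 0.05, and a
    planted facility/attendant inconsistency rate of 4 per 10,000.
    """

    rows: int = 10
    cols: int = 11
    n_births: int = 12200
    #: era shares of births, from the pooled table denominators
    #: (5056, 4671, 1612, 887) / 12226
    period_shares: tuple[float, float, float, float] = (0.4135, 0.3821, 0.1319, 0.0725)
    inconsistency_rate: float = 0.0004
    seed: int = 0
    intercept: float = 0.0
    policy_log_or: tuple[float, float, float] = (
        math.log(1.17),
        math.log(1.67),
        math.log(1.65),
    )
    alpha: dict[str, float] = field(default_factory=_default_alpha)
    category_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_category_probs
    )
    tau2_str: float = 1.0
    tau2_unstr: float = 0.05
    #: deterministic north-south gradient added to the structured effect
    band_offsets: dict[str, float] = field(
        default_factory=lambda: {"north": -1.4, "central": 0.3, "south": 0.6}
    )
    #: regions treated as "deprived" for the staged free-delivery rollout
    deprived_regions: frozenset = frozenset({"north"})
    include_smooths: bool = True

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.n_births < 1:
            raise ValueError("invalid dimensions")
        if abs(sum(self.period_shares) - 1.0) > 1e-9:
            raise ValueError("period shares must sum to 1")
        if not 0 <= self.inconsistency_rate < 1:
            raise ValueError("inconsistency_rate must be in [0, 1)")

    @property
    def n_districts(self) -> int:
        return self.rows * self.cols


# true (uncentred) smooth shapes: increasing saturating in age and antenatal
# visits, decreasing in parity and facility distance
_RAW_SMOOTHS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "maternal_age": lambda a: 0.6 * np.tanh((np.asarray(a, float) - 26.0) / 7.0),
    "parity": lambda p: -0.35 * np.log1p(np.asarray(p, float) - 1.0),
    "anc_visits": lambda v: 0.9 * (1.0 - np.exp(-np.asarray(v, float) / 2.5)),
    "distance_km": lambda d: -0.8 * (np.asarray(d, float) / (np.asarray(d, float) + 8.0)),
}


def _period_month_window(period: PolicyPeriod, deprived: bool) -> tuple[int, int]:
    lo, hi = ANALYSIS_WINDOW
    if period is PolicyPeriod.cash_and_carry:
        return lo, FREE_ANTENATAL_START - 1
    if period is PolicyPeriod.free_antenatal:
        end = (FREE_DELIVERY_START_DEPRIVED if deprived else FREE_DELIVERY_START_NATIONAL)
        return FREE_ANTENATAL_START, end - 1
    if period is PolicyPeriod.free_delivery:
        start = (FREE_DELIVERY_START_DEPRIVED if deprived else FREE_DELIVERY_START_NATIONAL)
        return start, NHIS_START - 1
    return NHIS_START, hi


def generate_survey(
    config: GeneratorConfig,
    graph: DistrictGraph | None = None,
    seed: int | None = None,
) -> tuple[SurveyTable, TruthBundle]:
    """Simulate the geoadditive model forward and return data plus truth.

    Covariates are drawn independently (age bounded-continuous, parity and
    antenatal visits counts, distance right-skewed positive); the predictor
    is assembled exactly as the fitted model specifies; outcomes are
    Bernoulli(logistic(eta)); the facility flag equals the outcome except
    for a planted inconsistency fraction. Byte-reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if graph is None:
        graph = make_lattice_graph(config.rows, config.cols)
    s = graph.n_districts
    idx = graph.index_of()
    n = config.n_births

    # spatial truth: CAR field + deterministic band gradient, centred per component
    # (tau2_str = 0 expresses a spatially null truth)
    car = (
        sample_car_effects(graph, config.tau2_str, rng)
        if config.tau2_str > 0
        else np.zeros(s)
    )
    offsets = np.array(
        [config.band_offsets.get(graph.region_of[d], 0.0) for d in graph.district_ids]
    )
    f_str = car + offsets
    for comp in graph.components():
        rows = [idx[d] for d in comp]
        f_str[rows] -= f_str[rows].mean()
    f_unstr = rng.normal(0.0, math.sqrt(config.tau2_unstr), s)
    f_unstr -= f_unstr.mean()

    district_pos = rng.integers(0, s, n)
    district = np.array(graph.district_ids)[district_pos]
    region = np.array([graph.region_of[d] for d in district])

    periods = np.array(
        rng.choice(len(PolicyPeriod), size=n, p=list(config.period_shares))
    )
    period_order = list(PolicyPeriod)
    deprived_mask = np.isin(region, list(config.deprived_regions))
    month = np.empty(n, dtype=int)
    for p_i, period in enumerate(period_order):
        for dep in (False, True):
            m = (periods == p_i) & (deprived_mask == dep)
            if m.any():
                lo, hi = _period_month_window(period, dep)
                month[m] = rng.integers(lo, hi + 1, int(m.sum()))

    age = np.clip(rng.normal(28.0, 6.5, n), 15.0, 49.0)
    parity = 1 + rng.poisson(2.3, n)
    anc = rng.poisson(4.0, n)
    dist = rng.lognormal(1.2, 1.0, n)

    cats = {}
    for var, probs in config.category_probs.items():
        levels = list(probs)
        cats[var] = np.array(levels)[
            rng.choice(len(levels), size=n, p=list(probs.values()))
        ]

    eta = np.full(n, config.intercept)
    for var, values in cats.items():
        for level in np.unique(values):
            coef = config.alpha.get(f"{var}[{level}]", 0.0)
            if coef:
                eta[values == level] += coef
    policy_lor = dict(
        zip(("free_antenatal", "free_delivery", "nhis"), config.policy_log_or)
    )
    for p_i, period in enumerate(period_order):
        coef = policy_lor.get(period.value, 0.0)
        if coef:
            eta[periods == p_i] += coef

    covariates = {
        "maternal_age": age,
        "parity": parity.astype(float),
        "anc_visits": anc.astype(float),
        "distance_km": dist,
    }
    smooth_functions: dict[str, Callable] = {}
    if config.include_smooths:
        for name, raw in _RAW_SMOOTHS.items():
            centre = float(raw(covariates[name]).mean())
            fn = (lambda raw=raw, centre=centre: lambda x: raw(x) - centre)()
            smooth_functions[name] = fn
            eta += fn(covariates[name])

    eta += f_str[district_pos] + f_unstr[district_pos]

    outcome = (rng.random(n) < expit(eta)).astype(int)
    facility = outcome.copy()
    skilled = np.flatnonzero(outcome == 1)
    n_inconsistent = rng.binomial(n, config.inconsistency_rate)
    if n_inconsistent > 0 and skilled.size:
        flip = rng.choice(skilled, size=min(n_inconsistent, skilled.size), replace=False)
        facility[flip] = 0

    df = pd.DataFrame(
        {
            "outcome": outcome,
            "facility_birth": facility,
            "birth_month": month,
            "district": district,
            "region": region,
            **cats,
            "maternal_age": age,
            "parity": parity,
            "anc_visits": anc,
            "distance_km": dist,
        }
    )
    table = SurveyTable.from_dataframe(df, graph=graph)
    table = table.with_policy_periods(config.deprived_regions)
    truth = TruthBundle(
        intercept=config.intercept,
        alpha=dict(config.alpha),
        policy_log_or=policy_lor,
        smooth_functions=smooth_functions,
        f_str=f_str,
        f_unstr=f_unstr,
        tau2_str=config.tau2_str,
        tau2_unstr=config.tau2_unstr,
        district_ids=graph.district_ids,
        eta=eta,
    )
    return table, truth


# --------------------------------------------------------------------------
# road networks for the accessibility stage

def generate_road_network(
    n_nodes: int = 30,
    n_facilities: int = 3,
    n_clusters: int = 10,
    extent_km: float = 100.0,
    seed: int | None = None,
):
    """Random connected planar road network with facilities and survey clusters.

    Road edges come from the Delaunay triangulation of random junctions with
    lengths inflated above the straight-line distance (roads bend). Cluster
    points are scattered off-network; the true nearest-facility network
    distance for each cluster (snap offset + shortest path) is recorded for
    testing.

    Returns ``(RoadNetwork, truth)`` where truth maps cluster id ->
    (distance_km, facility id).
    """
    import networkx as nx
    from scipy.spatial import Delaunay

    from .accessibility import RoadNetwork

    if n_facilities < 1:
        raise ValueError("need at least one facility")
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes for a planar network")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, extent_km, (n_nodes, 2))
    tri = Delaunay(pts)
    edge_set = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edge_set.add((a, b))
    edges = []
    for a, b in sorted(edge_set):
        straight = float(np.hypot(*(pts[a] - pts[b])))
        edges.append((f"n{a}", f"n{b}", straight * float(1.0 + 0.3 * rng.random())))

    nodes = {f"n{i}": (float(x), float(y)) for i, (x, y) in enumerate(pts)}
    fac_idx = rng.choice(n_nodes, size=n_facilities, replace=False)
    facilities = {f"n{i}" for i in fac_idx}
    clusters = {
        f"c{j}": tuple(rng.uniform(0.0, extent_km, 2).tolist())
        for j in range(n_clusters)
    }
    net = RoadNetwork(nodes, edges, facilities, clusters)

    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    dist_map, path_map = nx.multi_source_dijkstra(g, facilities, weight="weight")
    coords = np.array([nodes[f"n{i}"] for i in range(n_nodes)])
    truth = {}
    for cid, (cx, cy) in clusters.items():
        offs = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
        snap = int(np.argmin(offs))
        node = f"n{snap}"
        truth[cid] = (float(offs[snap] + dist_map[node]), path_map[node][0])
    return net, truth
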