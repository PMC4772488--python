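"""Domain types, survey/adjacency IO, policy-period assignment and record filtering.

The analysis unit is one birth; births nest in districts, districts carry an
adjacency structure (the support of the structured spatial effect) and a region
label (which determines when the staged free-delivery policy reached them).

Calendar months are held as CMC integers (century month code, Jan-1900 = 1),
the convention used by DHS birth histories.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing from the survey file or column map."""


class InputError(ValueError):
    """The input file is empty or structurally unreadable."""


class UnknownDistrictError(KeyError):
    """A record or edge references a district absent from the district list."""


class AdjacencyFormatError(ValueError):
    """Malformed adjacency line (wrong token count or self-loop)."""


# --------------------------------------------------------------------------
# calendar helpers

def cmc(year: int, month: int) -> int:
    """Century month code: Jan-1900 = 1."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1..12, got {month}")
    return (year - 1900) * 12 + month


#: analysis window: births Nov-1990 .. Oct-2008
ANALYSIS_WINDOW = (cmc(1990, 11), cmc(2008, 10))

FREE_ANTENATAL_START = cmc(1998, 6)      # cash & carry ends May-1998
FREE_DELIVERY_START_DEPRIVED = cmc(2003, 9)
FREE_DELIVERY_START_NATIONAL = cmc(2005, 4)
NHIS_START = cmc(2007, 7)                # post June-2007

#: the four most deprived regions, where free delivery care started Sep-2003
DEFAULT_DEPRIVED_REGIONS = frozenset(
    {"Northern", "Upper East", "Upper West", "Central"}
)


class PolicyPeriod(str, enum.Enum):
    """The four successive maternity-fee regimes."""

    cash_and_carry = "cash_and_carry"
    free_antenatal = "free_antenatal"
    free_delivery = "free_delivery"
    nhis = "nhis"


def assign_policy_period(
    birth_month: int,
    region: str,
    deprived_regions: frozenset[str] = DEFAULT_DEPRIVED_REGIONS,
    window: tuple[int, int] = ANALYSIS_WINDOW,
) -> PolicyPeriod:
    """Map a (calendar month, region) pair to its maternity-fee policy era.

    Boundaries are closed at the start and open at the end of each era. The
    free-delivery era begins Sep-2003 in the configured deprived regions and
    Apr-2005 elsewhere; months Sep-2003..Mar-2005 in non-deprived regions
    still belong to the free-antenatal era. The Jul..Oct-2008 NHIS premium
    exemption window is not a separate category.
    """
    lo, hi = window
    if not lo <= birth_month <= hi:
        raise ValueError(
            f"birth month {birth_month} outside analysis window {window}"
        )
    if birth_month < FREE_ANTENATAL_START:
        return PolicyPeriod.cash_and_carry
    if birth_month >= NHIS_START:
        return PolicyPeriod.nhis
    start_delivery = (
        FREE_DELIVERY_START_DEPRIVED
        if region in deprived_regions
        else FREE_DELIVERY_START_NATIONAL
    )
    if birth_month >= start_delivery:
        return PolicyPeriod.free_delivery
    return PolicyPeriod.free_antenatal


# --------------------------------------------------------------------------
# district graph

@dataclass(frozen=True)
class DistrictGraph:
    """Districts with symmetric adjacency and a district -> region map.

    Edges are stored as sorted id pairs; self-loops are rejected and edge
    endpoints must exist in ``district_ids``. Isolated districts are allowed
    (the ICAR prior pins their structured effect to zero) but reported.
    """

    district_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    region_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.district_ids) == 0:
            raise ValueError("graph needs at least one district")
        if len(set(self.district_ids)) != len(self.district_ids):
            raise ValueError("duplicate district ids")
        known = set(self.district_ids)
        for a, b in self.edges:
            if a == b:
                raise AdjacencyFormatError(f"self-loop on district {a!r}")
            if a not in known or b not in known:
                raise UnknownDistrictError(f"edge ({a!r}, {b!r}) names unknown district")

    @property
    def n_districts(self) -> int:
        return len(self.district_ids)

    def index_of(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.district_ids)}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.district_ids)
        g.add_edges_from(self.edges)
        return g

    def components(self) -> list[set[str]]:
        """Connected components (the ICAR sum-to-zero constraint is per component)."""
        import networkx as nx

        return [set(c) for c in nx.connected_components(self.to_networkx())]

    @property
    def n_components(self) -> int:
        return len(self.components())

    def degrees(self) -> dict[str, int]:
        deg = {d: 0 for d in self.district_ids}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def isolated_districts(self) -> list[str]:
        return [d for d, k in self.degrees().items() if k == 0]

    def neighbours(self, district: str) -> set[str]:
        if district not in set(self.district_ids):
            raise UnknownDistrictError(district)
        out = set()
        for a, b in self.edges:
            if a == district:
                out.add(b)
            elif b == district:
                out.add(a)
        return out


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_adjacency(
    path,
    ids: Sequence[str],
    region_of: Mapping[str, str] | None = None,
) -> DistrictGraph:
    """Read a whitespace-delimited edge list ("idA idB" per line).

    Duplicate lines collapse to a single edge; lines starting with '#' and
    blank lines are skipped. Isolated districts are permitted but reported
    via a warning.
    """
    if not ids:
        raise ValueError("district id list is empty")
    known = set(ids)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise AdjacencyFormatError(
                    f"{path}:{lineno}: expected 'idA idB', got {line!r}"
                )
            a, b = parts
            if a == b:
                raise AdjacencyFormatError(f"{path}:{lineno}: self-loop on {a!r}")
            if a not in known or b not in known:
                raise UnknownDistrictError(
                    f"{path}:{lineno}: edge names unknown district in {line!r}"
                )
            edges.add(_norm_edge(a, b))
    if region_of is None:
        region_of = {d: "" for d in ids}
    graph = DistrictGraph(tuple(ids), frozenset(edges), dict(region_of))
    isolated = graph.isolated_districts()
    if isolated:
        warnings.warn(f"{len(isolated)} isolated district(s): {isolated[:5]}")
    return graph


def write_adjacency(graph: DistrictGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a} {b}\n")


def queen_contiguity_from_geojson(path, id_property: str = "district") -> list[tuple[str, str]]:
    """Derive an edge list from polygon features sharing any boundary point."""
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = [(f["properties"][id_property], shape(f["geometry"])) for f in gj["features"]]
    edges = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if feats[i][1].intersects(feats[j][1]):
                edges.append(_norm_edge(feats[i][0], feats[j][0]))
    return edges


# --------------------------------------------------------------------------
# survey table

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "education": ("none", "primary", "secondary+"),
    "religion": ("christian", "muslim", "other"),
    "ethnicity": (
        "akan",
        "ga_dangbe",
        "ewe_guan",
        "mole_dagbane",
        "grussi_gruma_hausa",
        "other",
    ),
    "partner_education": ("none_dk", "primary", "secondary+"),
    "wealth": ("poorest", "poor", "middle", "rich", "richest"),
    "residence": ("urban", "rural"),
}

CONTINUOUS_COLUMNS = ("maternal_age", "parity", "anc_visits", "distance_km")

REQUIRED_COLUMNS = (
    "outcome",
    "facility_birth",
    "birth_month",
    "district",
    "region",
    *CATEGORY_LEVELS,
    *CONTINUOUS_COLUMNS,
)


class BirthRecord(NamedTuple):
    outcome: int
    facility_birth: int
    birth_month: int
    district: str
    region: str
    education: str
    religion: str
    ethnicity: str
    partner_education: str
    wealth: str
    residence: str
    maternal_age: float
    parity: int
    anc_visits: int
    distance_km: float


@dataclass
class SurveyTable:
    """Per-birth records plus a log of records excluded during validation.

    Backed by a pandas DataFrame with canonical column names; ``records``
    iterates typed rows. ``exclusion_log`` counts dropped rows per rule and
    always sums to (raw rows - retained rows).
    """

    df: pd.DataFrame
    exclusion_log: Counter = field(default_factory=Counter)
    window: tuple[int, int] = ANALYSIS_WINDOW

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[BirthRecord]:
        for row in self.df[list(REQUIRED_COLUMNS)].itertuples(index=False):
            yield BirthRecord(*row)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        graph: DistrictGraph | None = None,
        window: tuple[int, int] = ANALYSIS_WINDOW,
    ) -> "SurveyTable":
        """Validate and canonicalise a raw frame, logging every exclusion.

        Rules, applied jointly (a row failing several rules is counted once,
        under the first failing rule): unparseable numerics, outcome or
        facility flag outside {0,1}, unknown category label, parity < 1,
        negative counts/distances, birth month outside the analysis window,
        unknown district. Missing partner's education merges into the
        "none_dk" base level; any other missing value drops the record.
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise InputError("survey file contains no data rows")

        out = df.copy()
        log: Counter = Counter()

        # partner's education: missing -> base level (Don't know / none)
        pe = out["partner_education"]
        out["partner_education"] = pe.where(pe.notna(), "none_dk")

        for col in ("outcome", "facility_birth", "birth_month", "parity", "anc_visits"):
            out[col] = pd.to_numeric(out[col], errors="coerce")
        for col in ("maternal_age", "distance_km"):
            out[col] = pd.to_numeric(out[col], errors="coerce")

        reasons = []  # ordered (label, boolean mask of bad rows)
        num_cols = ["outcome", "facility_birth", "birth_month", *CONTINUOUS_COLUMNS]
        reasons.append(("unparseable", out[num_cols].isna().any(axis=1)))
        reasons.append(("invalid_outcome", ~out["outcome"].isin([0, 1])))
        reasons.append(("invalid_facility_flag", ~out["facility_birth"].isin([0, 1])))
        for col, levels in CATEGORY_LEVELS.items():
            reasons.append((f"invalid_{col}", ~out[col].isin(levels)))
        reasons.append(("parity_lt_1", out["parity"] < 1))
        reasons.append(("negative_anc_visits", out["anc_visits"] < 0))
        reasons.append(("negative_distance", out["distance_km"] < 0))
        reasons.append(
            (
                "month_outside_window",
                (out["birth_month"] < window[0]) | (out["birth_month"] > window[1]),
            )
        )
        if graph is not None:
            reasons.append(("unknown_district", ~out["district"].isin(graph.district_ids)))

        bad = pd.Series(False, index=out.index)
        for label, mask in reasons:
            mask = mask.fillna(True) if mask.dtype != bool else mask
            newly = mask & ~bad
            if newly.any():
                log[label] += int(newly.sum())
            bad |= mask

        kept = out.loc[~bad].reset_index(drop=True)
        for col in ("outcome", "facility_birth", "birth_month", "parity", "anc_visits"):
            kept[col] = kept[col].astype(int)
        table = cls(kept, log, window)
        assert sum(log.values()) == len(df) - len(kept)
        return table

    def with_policy_periods(
        self,
        deprived_regions: frozenset[str] = DEFAULT_DEPRIVED_REGIONS,
    ) -> "SurveyTable":
        """Return a copy with a ``policy_period`` column assigned per record."""
        df = self.df.copy()
        df["policy_period"] = [
            assign_policy_period(m, r, deprived_regions, self.window).value
            for m, r in zip(df["birth_month"], df["region"])
        ]
        return SurveyTable(df, Counter(self.exclusion_log), self.window)


def read_survey(path, schema: Mapping[str, str] | None = None, sep: str | None = ",",
                graph: DistrictGraph | None = None,
                window: tuple[int, int] = ANALYSIS_WINDOW) -> SurveyTable:
    """Read a delimited survey file into a validated :class:`SurveyTable`.

    ``schema`` maps canonical field names to the file's column names; omit it
    when the file already uses canonical names. Rows violating domain rules
    are logged in ``exclusion_log``, never silently dropped.
    """
    try:
        raw = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty survey file: {path}") from exc
    if schema:
        missing_src = [v for v in schema.values() if v not in raw.columns]
        if missing_src:
            raise SchemaError(f"schema names absent column(s): {missing_src}")
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    return SurveyTable.from_dataframe(raw, graph=graph, window=window)


def write_survey(table: SurveyTable, path) -> None:
    table.df.to_csv(path, index=False)


def filter_inconsistent(table: SurveyTable) -> tuple[SurveyTable, float]:
    """Drop records reporting a skilled attendant outside a facility.

    These contradictory reports (facility_birth = 0, outcome = 1) are treated
    as recall error and removed; the returned fraction is removed/raw. The
    operation is idempotent.
    """
    bad = (table.df["facility_birth"] == 0) & (table.df["outcome"] == 1)
    n_raw = len(table.df)
    kept = table.df.loc[~bad].reset_index(drop=True)
    log = Counter(table.exclusion_log)
    if int(bad.sum()):
        log["inconsistent_facility_outcome"] += int(bad.sum())
    if len(kept) == 0:
        warnings.warn("all records removed by consistency filter")
    return SurveyTable(kept, log, table.window), bad.sum() / n_raw if n_raw else 0.0
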