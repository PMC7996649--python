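"""Readers, writers and domain containers for the tabular and graph formats.

All interchange files are comma-separated UTF-8 with a mandatory header row
and ``.`` decimal mark.  Three tables are understood:

``facilities.csv``
    One row per health facility (the roster), including non-surveyed
    referral destinations, which must still carry the model covariates.
``referrals.csv``
    One row per (sender, receiver, condition) referral report.
``distances.csv``
    Square pairwise road-distance matrix in km, keyed by facility id on
    both axes.

Validation is total: every malformed input raises :class:`ValidationError`
naming the offending row/field; nothing is silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

TIERS = ("dispensary", "health_centre", "hospital")
OWNERSHIPS = ("public", "faith_based", "private")
DOMAINS = ("childcare", "ncd")

FACILITY_COLUMNS = [
    "facility_id", "name", "district", "tier", "ownership", "surveyed",
    "lon", "lat", "delivery_beds", "patient_beds", "rooms", "motorcycles",
    "ambulances", "catchment_population", "facility_deliveries_3m",
    "outpatient_visits_3m", "rch_visits_3m",
]
REFERRAL_COLUMNS = ["sender_id", "receiver_id", "condition_category", "domain", "n_referrals"]

# Count-valued facility covariates that must be non-negative integers.
COUNT_FIELDS = (
    "delivery_beds", "patient_beds", "rooms", "motorcycles", "ambulances",
    "facility_deliveries_3m",
)


@dataclass(frozen=True)
class Facility:
    """A health facility node with tier, ownership and capacity covariates."""

    facility_id: str
    name: str
    district: str
    tier: str
    ownership: str
    surveyed: bool
    lon: float
    lat: float
    delivery_beds: int
    patient_beds: int
    rooms: int
    motorcycles: int
    ambulances: int
    catchment_population: int
    facility_deliveries_3m: int
    outpatient_visits_3m: int | None = None
    rch_visits_3m: int | None = None

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValidationError(
                f"facility {self.facility_id!r}: unknown tier {self.tier!r} "
                f"(expected one of {TIERS})"
            )
        if self.ownership not in OWNERSHIPS:
            raise ValidationError(
                f"facility {self.facility_id!r}: unknown ownership {self.ownership!r} "
                f"(expected one of {OWNERSHIPS})"
            )
        for field in COUNT_FIELDS:
            if getattr(self, field) < 0:
                raise ValidationError(
                    f"facility {self.facility_id!r}: negative count {field}={getattr(self, field)}"
                )
        if self.catchment_population < 1:
            raise ValidationError(
                f"facility {self.facility_id!r}: catchment_population must be >= 1"
            )


class Roster(Sequence):
    """Ordered, keyed collection of :class:`Facility` rows.

    Row order is preserved from the source table and defines the canonical
    node order of every network built from this roster.
    """

    def __init__(self, facilities: Sequence[Facility]):
        self._facilities = list(facilities)
        self._index: dict[str, int] = {}
        for pos, fac in enumerate(self._facilities):
            if fac.facility_id in self._index:
                raise ValidationError(
                    f"duplicate facility_id {fac.facility_id!r} (rows "
                    f"{self._index[fac.facility_id] + 1} and {pos + 1})"
                )
            self._index[fac.facility_id] = pos

    def __len__(self) -> int:
        return len(self._facilities)

    def __getitem__(self, item):
        if isinstance(item, str):
            return self._facilities[self.position(item)]
        return self._facilities[item]

    def __iter__(self):
        return iter(self._facilities)

    def __contains__(self, facility_id) -> bool:
        return facility_id in self._index

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f.facility_id for f in self._facilities)

    def position(self, facility_id: str) -> int:
        try:
            return self._index[facility_id]
        except KeyError:
            raise ValidationError(f"facility {facility_id!r} not in roster") from None

    def covariate(self, attribute: str) -> np.ndarray:
        """Vector of a numeric covariate in roster order; None values stay NaN."""
        vals = [getattr(f, attribute) for f in self._facilities]
        return np.array([np.nan if v is None else float(v) for v in vals])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(f) for f in self._facilities],
                            columns=FACILITY_COLUMNS)


@dataclass(frozen=True)
class ReferralRecord:
    """One reported referral flow between two facilities.

    ``n_referrals`` keeps the reported multiplicity; network assembly
    deliberately ignores it (the networks are binary and non-weighted).
    """

    sender_id: str
    receiver_id: str
    condition_category: str
    domain: str
    n_referrals: int = 1

    def __post_init__(self):
        if self.sender_id == self.receiver_id:
            raise ValidationError(f"self-referral forbidden: {self.sender_id!r}")
        if self.domain not in DOMAINS:
            raise ValidationError(
                f"unknown domain {self.domain!r} (expected one of {DOMAINS})"
            )
        if self.n_referrals < 1:
            raise ValidationError("n_referrals must be a positive integer")


class DistanceMatrix:
    """Symmetric pairwise road distances (km) over an ordered facility set."""

    def __init__(self, ids: Sequence[str], values: np.ndarray, provenance: str = "unspecified"):
        values = np.asarray(values, dtype=float)
        ids = tuple(ids)
        if values.shape != (len(ids), len(ids)):
            raise ValidationError(
                f"distance matrix shape {values.shape} does not match {len(ids)} ids"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(f"negative distance between {ids[i]!r} and {ids[j]!r}")
        if np.any(np.diag(values) != 0):
            i = int(np.argwhere(np.diag(values) != 0)[0])
            raise ValidationError(f"non-zero diagonal for facility {ids[i]!r}")
        asym = np.abs(values - values.T)
        if asym.max() > 1e-6:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"distance matrix asymmetric by {asym[i, j]:g} km for pair "
                f"({ids[i]!r}, {ids[j]!r})"
            )
        self.ids = ids
        # within-tolerance asymmetry is averaged away; a single dyadic
        # coefficient presumes x_ij = x_ji
        self.values = (values + values.T) / 2.0
        self.provenance = provenance
        self._index = {fid: k for k, fid in enumerate(ids)}

    def lookup(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        missing = [fid for fid in ids if fid not in self._index]
        if missing:
            raise ValidationError(
                "distance matrix is missing facilities: " + ", ".join(repr(m) for m in missing)
            )
        idx = [self._index[fid] for fid in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)], self.provenance)


def _parse_bool(value, row: int) -> bool:
    token = str(value).strip().lower()
    if token in {"1", "true"}:
        return True
    if token in {"0", "false"}:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {value!r}")


def _parse_int(value, row: int, field: str, optional: bool = False):
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        if optional:
            return None
        raise ValidationError(f"row {row}: missing value for {field!r}")
    try:
        return int(float(value))
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: cannot parse integer {field}={value!r}") from None


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_facility_table(path) -> Roster:
    """Read and validate a ``facilities.csv`` roster.

    Row order is preserved. A header-only file yields an empty roster.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, FACILITY_COLUMNS, path)
    facilities = []
    for pos, rec in enumerate(frame.to_dict("records")):
        row = pos + 2  # 1-based, after header
        if rec["facility_id"].strip() == "":
            raise ValidationError(f"row {row}: missing facility_id")
        facilities.append(Facility(
            facility_id=rec["facility_id"].strip(),
            name=rec["name"],
            district=rec["district"].strip(),
            tier=rec["tier"].strip(),
            ownership=rec["ownership"].strip(),
            surveyed=_parse_bool(rec["surveyed"], row),
            lon=float(rec["lon"]),
            lat=float(rec["lat"]),
            delivery_beds=_parse_int(rec["delivery_beds"], row, "delivery_beds"),
            patient_beds=_parse_int(rec["patient_beds"], row, "patient_beds"),
            rooms=_parse_int(rec["rooms"], row, "rooms"),
            motorcycles=_parse_int(rec["motorcycles"], row, "motorcycles"),
            ambulances=_parse_int(rec["ambulances"], row, "ambulances"),
            catchment_population=_parse_int(rec["catchment_population"], row, "catchment_population"),
            facility_deliveries_3m=_parse_int(rec["facility_deliveries_3m"], row, "facility_deliveries_3m"),
            outpatient_visits_3m=_parse_int(rec["outpatient_visits_3m"], row, "outpatient_visits_3m", optional=True),
            rch_visits_3m=_parse_int(rec["rch_visits_3m"], row, "rch_visits_3m", optional=True),
        ))
    return Roster(facilities)


def write_facility_table(roster: Roster, path) -> None:
    frame = roster.to_frame().copy()
    frame["surveyed"] = frame["surveyed"].map({True: "true", False: "false"})
    frame.to_csv(path, index=False)


def read_referral_records(path) -> list[ReferralRecord]:
    """Read ``referrals.csv``; a blank ``n_referrals`` defaults to 1."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, REFERRAL_COLUMNS, path)
    records = []
    for pos, rec in enumerate(frame.to_dict("records")):
        row = pos + 2
        n_ref = rec["n_referrals"].strip()
        try:
            records.append(ReferralRecord(
                sender_id=rec["sender_id"].strip(),
                receiver_id=rec["receiver_id"].strip(),
                condition_category=rec["condition_category"].strip(),
                domain=rec["domain"].strip(),
                n_referrals=1 if n_ref == "" else _parse_int(n_ref, row, "n_referrals"),
            ))
        except ValidationError as err:
            raise ValidationError(f"row {row}: {err}") from None
    return records


def write_referral_records(records: Sequence[ReferralRecord], path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=REFERRAL_COLUMNS)
    frame.to_csv(path, index=False)


def read_distance_matrix(path, roster: Roster) -> DistanceMatrix:
    """Read ``distances.csv`` and reorder it to roster order.

    The matrix must cover every roster facility (including non-surveyed
    referral destinations); entries are road distances in km, symmetric
    within a 1e-6 km tolerance and then symmetrized by averaging.
    """
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    if list(frame.index) != list(frame.columns):
        raise ValidationError(f"{path}: row and column facility ids differ")
    matrix = DistanceMatrix(list(frame.index), frame.to_numpy(dtype=float))
    return matrix.reorder(roster.ids)


def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, index=list(matrix.ids), columns=list(matrix.ids))
    frame.to_csv(path, index_label="facility_id")


def write_network_graphml(net, path, roster: Roster | None = None) -> None:
    """Export a :class:`~refnet.network.ReferralNetwork` as GraphML.

    Node order is stored in an explicit ``order`` attribute so the
    round-trip through :func:`read_network_graphml` is lossless.
    """
    graph = nx.DiGraph(district=net.district, domain=net.domain)
    for pos, fid in enumerate(net.node_ids):
        attrs = {"order": pos}
        if roster is not None and fid in roster:
            fac = roster[fid]
            attrs.update(tier=fac.tier, ownership=fac.ownership, district=fac.district)
        graph.add_node(fid, **attrs)
    for i, j in zip(*np.nonzero(net.adjacency)):
        graph.add_edge(net.node_ids[int(i)], net.node_ids[int(j)])
    nx.write_graphml(graph, path)


def read_network_graphml(path):
    from .network import ReferralNetwork  # local import to avoid a cycle

    graph = nx.read_graphml(path)
    nodes = sorted(graph.nodes, key=lambda fid: graph.nodes[fid].get("order", 0))
    index = {fid: k for k, fid in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    for u, v in graph.edges:
        adj[index[u], index[v]] = 1
    return ReferralNetwork(
        district=graph.graph.get("district", ""),
        domain=graph.graph.get("domain", ""),
        node_ids=tuple(nodes),
        adjacency=adj,
    )


def write_fit_json(results, path) -> None:
    """Serialize an :class:`~refnet.ergm.ErgmResults` to JSON."""
    Path(path).write_text(json.dumps(results.to_dict(), indent=2))
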