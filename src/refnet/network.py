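"""Assembly of binary directed referral networks.

A referral network for one district and care domain is a simple directed
graph over the district's facilities plus any external referral
destinations: ``y_ij = 1`` iff at least one referral in any condition
category was reported from facility *i* to facility *j* in the study
window.  Multiplicities and condition categories collapse to a single tie
(binary, non-weighted coding); self-ties are impossible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .errors import ValidationError
from .io import ReferralRecord, Roster


@dataclass(frozen=True)
class ReferralNetwork:
    """Binary directed referral network for one district x care domain."""

    district: str
    domain: str
    node_ids: tuple[str, ...]
    adjacency: np.ndarray  # n x n uint8, zero diagonal

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=np.uint8)
        n = len(self.node_ids)
        if adj.shape != (n, n):
            raise ValidationError(f"adjacency shape {adj.shape} does not match {n} nodes")
        if np.any(np.diag(adj) != 0):
            raise ValidationError("self-ties are forbidden (non-zero diagonal)")
        if np.any(adj > 1):
            raise ValidationError("adjacency entries must be 0/1")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def n_dyads(self) -> int:
        return self.n * (self.n - 1)

    @property
    def in_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    @property
    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def position(self, facility_id: str) -> int:
        try:
            return self.node_ids.index(facility_id)
        except ValueError:
            raise ValidationError(f"facility {facility_id!r} not in network") from None

    def edges(self) -> list[tuple[str, str]]:
        return [(self.node_ids[int(i)], self.node_ids[int(j)])
                for i, j in zip(*np.nonzero(self.adjacency))]

    def with_adjacency(self, adjacency: np.ndarray) -> "ReferralNetwork":
        return ReferralNetwork(self.district, self.domain, self.node_ids, adjacency)


def assemble_network(records: Sequence[ReferralRecord], roster: Roster,
                     district: str, domain: str) -> ReferralNetwork:
    """Build the binary network for one district and care domain.

    The node set is every roster facility of ``district`` (isolates
    retained — the model has an isolates term) plus any external facility
    that receives a matching referral from an in-district sender.  Node
    order follows roster order, which makes assembly deterministic and
    order-independent in the records.
    """
    for rec in records:
        if rec.sender_id not in roster:
            raise ValidationError(f"record sender {rec.sender_id!r} not in roster")
        if rec.receiver_id not in roster:
            raise ValidationError(f"record receiver {rec.receiver_id!r} not in roster")

    in_district = {f.facility_id for f in roster if f.district == district}
    matching = [r for r in records if r.domain == domain and r.sender_id in in_district]
    externals = {r.receiver_id for r in matching if r.receiver_id not in in_district}

    chosen = in_district | externals
    node_ids = tuple(fid for fid in roster.ids if fid in chosen)
    index = {fid: k for k, fid in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)), dtype=np.uint8)
    for rec in matching:
        adj[index[rec.sender_id], index[rec.receiver_id]] = 1
    return ReferralNetwork(district=district, domain=domain, node_ids=node_ids, adjacency=adj)


def filter_by_category(records: Sequence[ReferralRecord],
                       categories: Sequence[str]) -> list[ReferralRecord]:
    """Subset records to the given condition categories, preserving order.

    Unknown categories produce a warning (an empty subset is allowed);
    this supports per-condition network assembly.
    """
    present = {r.condition_category for r in records}
    wanted = set(categories)
    unknown = wanted - present
    if unknown:
        warnings.warn(
            "categories not present in records: " + ", ".join(sorted(unknown)),
            stacklevel=2,
        )
    return [r for r in records if r.condition_category in wanted]
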