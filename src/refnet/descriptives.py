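"""Network- and node-level descriptive statistics.

Density, tier-to-tier referral flows, referral rates per visit volume,
degree summaries and betweenness centrality — the quantities used to
judge whether secondary-level facilities (health centres) act as
gatekeepers between primary care (dispensaries) and hospitals.

Betweenness here is the raw (unnormalized) directed count with
fractional attribution across tied shortest paths and endpoints
excluded; on sparse referral networks it takes small integer-ish values
and operationalizes "lies on referral chains".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Roster, TIERS
from .network import ReferralNetwork


@dataclass(frozen=True)
class TierFlowTable:
    """Tie counts by ordered (sender tier, receiver tier) pair.

    ``to_private_or_faith_based`` counts ties whose receiver is privately
    or faith-based owned; ``cross_district`` counts ties whose receiver's
    home district differs from the sender's.
    """

    flows: dict[tuple[str, str], int]
    to_private_or_faith_based: int
    cross_district: int
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sender_tier": s, "receiver_tier": r, "count": c}
                for (s, r), c in sorted(self.flows.items())]
        return pd.DataFrame(rows, columns=["sender_tier", "receiver_tier", "count"])


@dataclass(frozen=True)
class DegreeSummary:
    """Per-node in/out-degree plus the in-degree distribution D_k."""

    node_ids: tuple[str, ...]
    in_degree: np.ndarray
    out_degree: np.ndarray

    @property
    def in_degree_distribution(self) -> np.ndarray:
        """D_k = number of nodes with in-degree k, for k = 0..n-1."""
        n = len(self.node_ids)
        return np.bincount(self.in_degree, minlength=n)[:n]


@dataclass(frozen=True)
class CentralityTable:
    """Betweenness and in-degree scores per node."""

    node_ids: tuple[str, ...]
    in_degree: np.ndarray
    betweenness: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "facility_id": self.node_ids,
            "in_degree": self.in_degree,
            "betweenness": self.betweenness,
        })


def density(net: ReferralNetwork) -> float:
    """Directed density: existing ties out of all n(n-1) possible ties."""
    if net.n < 2:
        raise ValidationError("density undefined for networks with fewer than 2 nodes")
    return net.n_edges / net.n_dyads


def tier_flow_counts(net: ReferralNetwork, roster: Roster) -> TierFlowTable:
    """Tabulate ties by sender/receiver tier, ownership and district."""
    tiers, districts, private_fb = {}, {}, {}
    for fid in net.node_ids:
        if fid not in roster:
            raise ValidationError(f"node {fid!r} has no roster entry (tier unknown)")
        fac = roster[fid]
        tiers[fid] = fac.tier
        districts[fid] = fac.district
        private_fb[fid] = fac.ownership in ("private", "faith_based")

    flows: dict[tuple[str, str], int] = {}
    n_pfb = n_cross = 0
    for sender, receiver in net.edges():
        key = (tiers[sender], tiers[receiver])
        flows[key] = flows.get(key, 0) + 1
        if private_fb[receiver]:
            n_pfb += 1
        if districts[receiver] != districts[sender]:
            n_cross += 1
    return TierFlowTable(flows=flows, to_private_or_faith_based=n_pfb,
                         cross_district=n_cross, total=net.n_edges)


def referral_rate(tie_count: int, visit_total: int, scale: int) -> float:
    """Referrals per ``scale`` visits (e.g. per 10 000 outpatient visits)."""
    if visit_total <= 0:
        raise ValidationError("referral rate undefined for zero visit volume")
    return tie_count / visit_total * scale


def degree_summary(net: ReferralNetwork) -> DegreeSummary:
    return DegreeSummary(node_ids=net.node_ids, in_degree=net.in_degree,
                         out_degree=net.out_degree)


def betweenness(net: ReferralNetwork) -> CentralityTable:
    """Raw directed betweenness (fractional attribution, endpoints excluded)."""
    graph = nx.DiGraph()
    graph.add_nodes_from(net.node_ids)
    graph.add_edges_from(net.edges())
    scores = nx.betweenness_centrality(graph, normalized=False)
    return CentralityTable(
        node_ids=net.node_ids,
        in_degree=net.in_degree,
        betweenness=np.array([scores[fid] for fid in net.node_ids]),
    )


def rank_centrality(table: CentralityTable, measure: str, top_k: int) -> list[tuple[str, float]]:
    """Top-k facilities by a centrality measure.

    Descending by score; ties broken by facility_id lexicographic order.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    if measure == "in_degree":
        scores = table.in_degree
    elif measure == "betweenness":
        scores = table.betweenness
    else:
        raise ValidationError(f"unknown centrality measure {measure!r}")
    order = sorted(range(len(table.node_ids)),
                   key=lambda k: (-float(scores[k]), table.node_ids[k]))
    return [(table.node_ids[k], float(scores[k])) for k in order[:top_k]]


def network_report(net: ReferralNetwork, roster: Roster) -> pd.DataFrame:
    """One-row-per-statistic summary in the style of the descriptive tables."""
    flows = tier_flow_counts(net, roster)
    rows = [
        ("n_nodes", net.n),
        ("n_referral_ties", net.n_edges),
        ("density", round(density(net), 3)),
        ("ties_to_private_or_faith_based", flows.to_private_or_faith_based),
        ("ties_outside_district", flows.cross_district),
    ]
    for (s, r), c in sorted(flows.flows.items()):
        rows.append((f"ties_{s}_to_{r}", c))
    return pd.DataFrame(rows, columns=["statistic", "value"])


def centrality_report(net: ReferralNetwork, top_k: int = 3) -> pd.DataFrame:
    """Ranked facilities by in-degree and betweenness (descriptive table shape)."""
    table = betweenness(net)
    rows = []
    for measure in ("in_degree", "betweenness"):
        for rank, (fid, score) in enumerate(rank_centrality(table, measure, top_k), start=1):
            rows.append({"measure": measure, "rank": rank,
                         "facility_id": fid, "score": score})
    return pd.DataFrame(rows, columns=["measure", "rank", "facility_id", "score"])


__all__ = [
    "TierFlowTable", "DegreeSummary", "CentralityTable", "density",
    "tier_flow_counts", "referral_rate", "degree_summary", "betweenness",
    "rank_centrality", "network_report", "centrality_report", "TIERS",
]
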