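import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from refnet import (Facility, ReferralNetwork, ReferralRecord, Roster,
                    assemble_network, fixture_from_table4)

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_facility(fid, tier="dispensary", district="testville", ownership="public",
                  **overrides):
    defaults = dict(
        facility_id=fid, name=fid, district=district, tier=tier,
        ownership=ownership, surveyed=True, lon=35.0, lat=-8.0,
        delivery_beds=1, patient_beds=3, rooms=4, motorcycles=0, ambulances=0,
        catchment_population=5000, facility_deliveries_3m=10,
        outpatient_visits_3m=500, rch_visits_3m=200,
    )
    defaults.update(overrides)
    return Facility(**defaults)


def make_roster(tiers, district="testville", **overrides):
    """Roster of facilities named F0, F1, ... with the given tier sequence."""
    return Roster([make_facility(f"F{k}", tier=t, district=district, **overrides)
                   for k, t in enumerate(tiers)])


def net_from_edges(roster, edges, district="testville", domain="childcare"):
    ids = roster.ids
    index = {fid: k for k, fid in enumerate(ids)}
    adj = np.zeros((len(ids), len(ids)), dtype=np.uint8)
    for s, r in edges:
        adj[index[s], index[r]] = 1
    return ReferralNetwork(district=district, domain=domain, node_ids=ids, adjacency=adj)


def random_digraph(rng, n, p=0.3):
    adj = (rng.random((n, n)) < p).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


@pytest.fixture(scope="session")
def kilolo_childcare():
    roster, records = fixture_from_table4("kilolo", "childcare")
    net = assemble_network(records, roster, "kilolo", "childcare")
    return roster, records, net


@pytest.fixture(scope="session")
def msalala_ncd():
    roster, records = fixture_from_table4("msalala", "ncd")
    net = assemble_network(records, roster, "msalala", "ncd")
    return roster, records, net


@pytest.fixture
def small_roster():
    return make_roster(["dispensary", "dispensary", "health_centre", "hospital"])
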