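"""Sufficient statistics and change statistics, term by term.

The load-bearing check is change/global consistency: for every term and
every dyad, the incremental change statistic must equal the global
statistic difference u(y+ij) - u(y-ij) to machine precision.
"""

import dataclasses

import numpy as np
import pytest

from refnet import (ErgmSpec, ReferralNetwork, TermDef, ValidationError,
                    change_statistics, network_statistics, parse_term,
                    parse_terms)

from conftest import make_roster, net_from_edges, random_digraph

ALL_TERMS = [
    TermDef("edges"),
    TermDef("isolates"),
    TermDef("gwidegree", decay=0.7),
    TermDef("gwidegree", decay=2.25),
    TermDef("edgecov", attribute="distance"),
    TermDef("edgecov", attribute="distance", transform="log1p"),
    TermDef("node_factor_in", attribute="tier", level="hospital"),
    TermDef("node_factor_combined", attribute="tier", level="health_centre"),
    TermDef("node_cov_in", attribute="delivery_beds"),
    TermDef("node_cov_out", attribute="rooms"),
    TermDef("node_cov_combined", attribute="patient_beds"),
    TermDef("node_cov_in", attribute="catchment_population", transform="log"),
]


def spec_for(roster, terms=None, seed=5):
    from refnet import DistanceMatrix
    rng = np.random.default_rng(seed)
    n = len(roster)
    base = rng.uniform(1, 30, size=(n, n))
    values = (base + base.T) / 2
    np.fill_diagonal(values, 0.0)
    distances = DistanceMatrix(roster.ids, values)
    return ErgmSpec(terms or ALL_TERMS, roster=roster, distances=distances)


def varied_roster(n, seed=3):
    rng = np.random.default_rng(seed)
    tiers = ["dispensary"] * (n - 2) + ["health_centre", "hospital"]
    roster = make_roster(tiers)
    return type(roster)([
        dataclasses.replace(
            f, delivery_beds=int(rng.integers(0, 5)),
            patient_beds=int(rng.integers(0, 40)), rooms=int(rng.integers(1, 12)),
            catchment_population=int(rng.integers(1000, 90000)))
        for f in roster])


class TestGlobalStatistics:
    def test_edges_statistic_on_fixture(self, kilolo_childcare):
        roster, _, net = kilolo_childcare
        spec = ErgmSpec([TermDef("edges")], roster=roster)
        assert network_statistics(net, spec)[0] == 33

    def test_isolates_on_empty_network(self):
        roster = make_roster(["dispensary"] * 10)
        spec = ErgmSpec([TermDef("isolates")], roster=roster)
        net = net_from_edges(roster, [])
        assert network_statistics(net, spec)[0] == 10

    def test_gwidegree_equals_d1_when_indegrees_at_most_one(self):
        # algebraic identity: e^a (1 - (1 - e^-a)) = 1
        roster = make_roster(["dispensary"] * 6)
        net = net_from_edges(roster, [("F0", "F1"), ("F2", "F3"), ("F4", "F5")])
        for decay in (0.5, 0.7, 1.2):
            spec = ErgmSpec([TermDef("gwidegree", decay=decay)], roster=roster)
            assert network_statistics(net, spec)[0] == pytest.approx(3.0)

    def test_edgecov_sums_covariate_over_ties(self):
        from refnet import DistanceMatrix
        roster = make_roster(["dispensary"] * 3)
        values = np.array([[0, 2.0, 3.0], [2.0, 0, 5.0], [3.0, 5.0, 0]])
        spec = ErgmSpec([TermDef("edgecov", attribute="distance")], roster=roster,
                        distances=DistanceMatrix(roster.ids, values))
        net = net_from_edges(roster, [("F0", "F1"), ("F1", "F2")])
        assert network_statistics(net, spec)[0] == pytest.approx(7.0)

    def test_nodal_terms_hand_computed(self):
        roster = varied_roster(4)
        net = net_from_edges(roster, [("F0", "F3"), ("F1", "F3")])
        spec = ErgmSpec([
            TermDef("node_cov_in", attribute="delivery_beds"),
            TermDef("node_cov_out", attribute="rooms"),
            TermDef("node_cov_combined", attribute="patient_beds"),
            TermDef("node_factor_in", attribute="tier", level="hospital"),
        ], roster=roster)
        u = network_statistics(net, spec)
        beds = [f.delivery_beds for f in roster]
        rooms = [f.rooms for f in roster]
        pbeds = [f.patient_beds for f in roster]
        assert u[0] == pytest.approx(2 * beds[3])
        assert u[1] == pytest.approx(rooms[0] + rooms[1])
        assert u[2] == pytest.approx(pbeds[0] + pbeds[1] + 2 * pbeds[3])
        assert u[3] == pytest.approx(2.0)  # both receivers are the hospital


class TestChangeStatistics:
    def test_edges_change_is_one_everywhere(self, small_roster):
        net = net_from_edges(small_roster, [("F0", "F3")])
        spec = ErgmSpec([TermDef("edges")], roster=small_roster)
        assert change_statistics(net, spec, (1, 2))[0] == 1.0

    def test_gwidegree_change_known_values(self):
        roster = make_roster(["dispensary"] * 4)
        spec = ErgmSpec([TermDef("gwidegree", decay=0.7)], roster=roster)
        empty = net_from_edges(roster, [])
        # receiver with prior in-degree 0
        assert change_statistics(empty, spec, (0, 1))[0] == pytest.approx(1.0)
        one_in = net_from_edges(roster, [("F2", "F1")])
        # receiver with prior in-degree 1: 1 - e^-0.7
        assert change_statistics(one_in, spec, (0, 1))[0] == pytest.approx(
            1.0 - np.exp(-0.7))

    def test_diagonal_rejected(self, small_roster):
        net = net_from_edges(small_roster, [])
        spec = ErgmSpec([TermDef("edges")], roster=small_roster)
        with pytest.raises(ValidationError):
            change_statistics(net, spec, (2, 2))

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_change_equals_global_difference_everywhere(self, n):
        """u(y+) - u(y-) == delta for all terms, dyads and several graphs."""
        roster = varied_roster(n)
        spec = spec_for(roster)
        rng = np.random.default_rng(n)
        for _ in range(6):
            adj = random_digraph(rng, n, p=0.3)
            net = ReferralNetwork("testville", "childcare", roster.ids, adj)
            bound = spec.bind(net)
            delta = bound.change_matrix()
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    plus = adj.copy(); plus[i, j] = 1
                    minus = adj.copy(); minus[i, j] = 0
                    diff = bound.statistics(plus) - bound.statistics(minus)
                    np.testing.assert_allclose(delta[i, j], diff, atol=1e-10,
                                               err_msg=f"dyad ({i},{j})")


class TestSpecValidation:
    def test_missing_covariate_names_node_and_attribute(self):
        roster = make_roster(["dispensary", "hospital"])
        roster = type(roster)([roster[0],
                               dataclasses.replace(roster[1], outpatient_visits_3m=None)])
        spec = ErgmSpec([TermDef("node_cov_in", attribute="outpatient_visits_3m")],
                        roster=roster)
        net = net_from_edges(roster, [("F0", "F1")])
        with pytest.raises(ValidationError, match="outpatient_visits_3m.*F1"):
            network_statistics(net, spec)

    @pytest.mark.parametrize("bad", [
        dict(kind="gwidegree"),                          # decay required
        dict(kind="edges", decay=0.5),                   # decay forbidden
        dict(kind="node_factor_in", attribute="tier", level="dispensary"),
        dict(kind="node_factor_in", attribute="tier", level="clinic"),
        dict(kind="edgecov"),                            # attribute required
        dict(kind="triangles"),
    ])
    def test_invalid_term_definitions(self, bad):
        with pytest.raises(ValidationError):
            TermDef(**bad)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            ErgmSpec([TermDef("edges"), TermDef("edges")])


class TestTermParsing:
    @pytest.mark.parametrize("text,expected", [
        ("edges", TermDef("edges")),
        ("gwidegree(0.7)", TermDef("gwidegree", decay=0.7)),
        ("edgecov(distance)", TermDef("edgecov", attribute="distance")),
        ("edgecov(distance,log1p)",
         TermDef("edgecov", attribute="distance", transform="log1p")),
        ("node_factor_in(hospital)",
         TermDef("node_factor_in", attribute="tier", level="hospital")),
        ("node_cov_in(catchment_population,log)",
         TermDef("node_cov_in", attribute="catchment_population", transform="log")),
    ])
    def test_parse_round_trip(self, text, expected):
        assert parse_term(text) == expected

    def test_parse_term_list(self):
        terms = parse_terms("edges + isolates + gwidegree(0.5)")
        assert [t.kind for t in terms] == ["edges", "isolates", "gwidegree"]
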