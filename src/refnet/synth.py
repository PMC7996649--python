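"""Synthetic district generators and deterministic table fixtures.

Two kinds of inputs are produced, both pure functions of (config, seed):

* **Simulated districts** — rosters with realistic tier mixes and
  covariate ranges, road-like distance matrices (Euclidean x a road
  detour factor) and referral networks drawn from an ERGM at known
  coefficients.  These drive the parameter-recovery and GOF studies.
* **Printed-table fixtures** — rosters and referral records that
  reproduce the published tier-to-tier referral breakdowns of the two
  study districts exactly (46 and 31 facilities; 40/3/3 and 25/4/2
  dispensaries / health centres / hospitals; 33/32/33/19 ties), with
  edges assigned to distinct dyads by round-robin over roster order.
  The published tables constrain only tier-pair counts, not which
  facilities connect, so the round-robin assignment is a deterministic
  stand-in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneracyError, ValidationError
from .io import DistanceMatrix, Facility, ReferralRecord, Roster
from .network import ReferralNetwork, assemble_network
from .sampler import run_chain
from .terms import ErgmSpec, TermDef

KM_PER_DEGREE = 111.32


def _default_ranges() -> dict:
    # per-tier (lo, hi) bounds consistent with the observed district
    # summaries: medians dominated by small dispensaries, hospitals at
    # the extreme of every capacity covariate
    return {
        "rooms": {"dispensary": (1, 8), "health_centre": (6, 15), "hospital": (15, 36)},
        "patient_beds": {"dispensary": (0, 6), "health_centre": (10, 50), "hospital": (60, 366)},
        "delivery_beds": {"dispensary": (0, 2), "health_centre": (2, 6), "hospital": (6, 17)},
        "motorcycles": {"dispensary": (0, 1), "health_centre": (0, 2), "hospital": (0, 2)},
        "ambulances": {"dispensary": (0, 1), "health_centre": (0, 2), "hospital": (0, 5)},
        "catchment_population": {"dispensary": (1200, 15000),
                                 "health_centre": (15000, 100000),
                                 "hospital": (100000, 950000)},
        "facility_deliveries_3m": {"dispensary": (1, 60), "health_centre": (60, 300),
                                   "hospital": (300, 1159)},
        "outpatient_visits_3m": {"dispensary": (100, 2000), "health_centre": (1000, 8000),
                                 "hospital": (5000, 30000)},
        "rch_visits_3m": {"dispensary": (50, 800), "health_centre": (400, 3000),
                          "hospital": (2000, 10000)},
    }


@dataclass
class SimConfig:
    """Configuration of one simulated district.

    ``extent_km`` is the side of the square the facilities occupy;
    ``road_factor`` (>= 1) inflates Euclidean distances into road-like
    ones.  ``hospital_placement`` emulates the two study geographies:
    ``"central"`` / ``"edge"`` (hospital in or near town) vs
    ``"distant"`` (closest hospital outside the populated square).
    """

    district: str = "simdistrict"
    tier_counts: tuple[int, int, int] = (40, 3, 3)
    extent_km: float = 30.0
    road_factor: float = 1.3
    hospital_placement: str = "central"
    base_lon: float = 35.5
    base_lat: float = -8.0
    covariate_ranges: dict = field(default_factory=_default_ranges)

    def __post_init__(self):
        if any(c < 0 for c in self.tier_counts) or sum(self.tier_counts) == 0:
            raise ValidationError("tier counts must be non-negative and sum to > 0")
        if self.tier_counts[1] + self.tier_counts[2] == 0:
            raise ValidationError("need at least one receiver-capable facility")
        if self.road_factor < 1.0:
            raise ValidationError("road factor must be >= 1")


def kilolo_config() -> SimConfig:
    return SimConfig(district="kilolo", tier_counts=(40, 3, 3), extent_km=60.0,
                     hospital_placement="edge", base_lon=35.7, base_lat=-8.1)


def msalala_config() -> SimConfig:
    cfg = SimConfig(district="msalala", tier_counts=(25, 4, 2), extent_km=45.0,
                    hospital_placement="distant", base_lon=32.5, base_lat=-3.7)
    cfg.covariate_ranges["catchment_population"]["dispensary"] = (610, 15000)
    cfg.covariate_ranges["catchment_population"]["hospital"] = (100000, 1535000)
    return cfg


def _draw_count(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Truncated negative-binomial-like draw within [lo, hi]."""
    if lo == hi:
        return int(lo)
    mean = lo + (hi - lo) / 4.0
    r = 2.0
    p = r / (r + max(mean - lo, 0.25))
    for _ in range(50):
        value = lo + rng.negative_binomial(r, p)
        if lo <= value <= hi:
            return int(value)
    return int(np.clip(value, lo, hi))


def _coords(rng: np.random.Generator, config: SimConfig, tier: str, idx: int,
            n_tier: int) -> tuple[float, float]:
    ext = config.extent_km
    if tier != "hospital":
        return rng.uniform(0, ext), rng.uniform(0, ext)
    if config.hospital_placement == "central":
        base = np.array([ext / 2, ext / 2])
    elif config.hospital_placement == "edge":
        base = np.array([ext, ext / 2])
    else:  # distant
        base = np.array([1.5 * ext, ext / 2])
    jitter = rng.uniform(-0.05 * ext, 0.05 * ext, size=2) + idx * 0.02 * ext
    return float(base[0] + jitter[0]), float(base[1] + jitter[1])


def generate_roster(config: SimConfig, seed: int) -> Roster:
    """Deterministic synthetic roster with the configured tier mix."""
    rng = np.random.default_rng(seed)
    prefix = config.district[:3].upper()
    tiers = (["dispensary"] * config.tier_counts[0]
             + ["health_centre"] * config.tier_counts[1]
             + ["hospital"] * config.tier_counts[2])
    counters = {"dispensary": 0, "health_centre": 0, "hospital": 0}
    short = {"dispensary": "D", "health_centre": "HC", "hospital": "H"}
    facilities = []
    lat_mid = config.base_lat
    for tier in tiers:
        counters[tier] += 1
        idx = counters[tier]
        x_km, y_km = _coords(rng, config, tier, idx - 1, config.tier_counts[
            ("dispensary", "health_centre", "hospital").index(tier)])
        ranges = config.covariate_ranges
        lo, hi = ranges["catchment_population"][tier]
        population = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        facilities.append(Facility(
            facility_id=f"{prefix}-{short[tier]}{idx:02d}",
            name=f"{config.district} {tier} {idx}",
            district=config.district,
            tier=tier,
            ownership="public",
            surveyed=True,
            lon=config.base_lon + x_km / (KM_PER_DEGREE * np.cos(np.radians(lat_mid))),
            lat=config.base_lat + y_km / KM_PER_DEGREE,
            delivery_beds=_draw_count(rng, *ranges["delivery_beds"][tier]),
            patient_beds=_draw_count(rng, *ranges["patient_beds"][tier]),
            rooms=_draw_count(rng, *ranges["rooms"][tier]),
            motorcycles=_draw_count(rng, *ranges["motorcycles"][tier]),
            ambulances=_draw_count(rng, *ranges["ambulances"][tier]),
            catchment_population=max(population, 1),
            facility_deliveries_3m=_draw_count(rng, *ranges["facility_deliveries_3m"][tier]),
            outpatient_visits_3m=_draw_count(rng, *ranges["outpatient_visits_3m"][tier]),
            rch_visits_3m=_draw_count(rng, *ranges["rch_visits_3m"][tier]),
        ))
    return Roster(facilities)


def euclidean_km(roster: Roster) -> np.ndarray:
    """Equirectangular great-circle approximation of pairwise distances."""
    lats = roster.covariate("lat")
    lons = roster.covariate("lon")
    lat_mid = np.radians(lats.mean())
    x = lons * KM_PER_DEGREE * np.cos(lat_mid)
    y = lats * KM_PER_DEGREE
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return np.sqrt(dx**2 + dy**2)


def generate_distances(roster: Roster, config: SimConfig, seed: int = 0) -> DistanceMatrix:
    """Road-like distances: Euclidean base times the road detour factor."""
    values = euclidean_km(roster) * config.road_factor
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(roster.ids, values, provenance="synthetic euclidean x road factor")


def generate_network(roster: Roster, distances: DistanceMatrix, theta,
                     terms: list[TermDef], seed: int, *, district: str | None = None,
                     domain: str = "childcare", burn_in: int | None = None,
                     attempts: int = 10) -> ReferralNetwork:
    """One ERGM draw over the roster's full node set after a long burn-in.

    Raises :class:`DegeneracyError` when the coefficients produce empty
    or complete draws in more than 90% of attempts.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValidationError("ground-truth coefficients must be finite")
    n = len(roster)
    empty = ReferralNetwork(district=district or roster[0].district, domain=domain,
                            node_ids=roster.ids,
                            adjacency=np.zeros((n, n), dtype=np.uint8))
    spec = ErgmSpec(terms, roster=roster, distances=distances)
    bound = spec.bind(empty)
    if burn_in is None:
        burn_in = 50 * n * (n - 1)
    rng = np.random.default_rng(seed)
    degenerate = 0
    for _ in range(attempts):
        chain_seed = int(rng.integers(2**31 - 1))
        _, nets = run_chain(bound, theta, burn_in=burn_in, interval=1,
                            n_samples=1, seed=chain_seed, keep_nets=True)
        net = empty.with_adjacency(nets[0])
        if 0 < net.n_edges < net.n_dyads:
            return net
        degenerate += 1
        if degenerate > 0.9 * attempts:
            break
    raise DegeneracyError(
        "generated networks were empty/complete in more than 90% of attempts; "
        "re-tune the ground-truth coefficients",
        payload={"attempts": attempts, "degenerate": degenerate})


# ---------------------------------------------------------------------------
# printed-table fixtures

_FLOWS = {
    ("kilolo", "childcare"): {
        ("dispensary", "health_centre"): 5,
        ("dispensary", "hospital"): 22,
        ("health_centre", "dispensary"): 1,
        ("health_centre", "hospital"): 2,
        ("hospital", "hospital"): 3,
    },
    ("msalala", "childcare"): {
        ("dispensary", "dispensary"): 3,
        ("dispensary", "health_centre"): 10,
        ("dispensary", "hospital"): 16,
        ("health_centre", "health_centre"): 1,
        ("health_centre", "hospital"): 2,
    },
    ("kilolo", "ncd"): {
        ("dispensary", "health_centre"): 2,
        ("dispensary", "hospital"): 25,
        ("health_centre", "hospital"): 1,
        ("hospital", "hospital"): 5,
    },
    ("msalala", "ncd"): {
        ("dispensary", "dispensary"): 2,
        ("dispensary", "health_centre"): 6,
        ("dispensary", "hospital"): 8,
        ("health_centre", "hospital"): 3,
    },
}

_CATEGORIES = {
    "childcare": ("fever", "pneumonia", "diarrhoea", "malnutrition"),
    "ncd": ("hypertension", "diabetes", "asthma"),
}

# External (non-surveyed) and non-public facilities, chosen to match the
# published roster-level counts: study district A has 3 faith-based and no
# private facilities among its 46 nodes; study district B has 1 private and
# 1 faith-based among 31.  All nodes keep the study-district label so every
# domain's network spans the full roster.
_FIXTURE_SEEDS = {"kilolo": 4601, "msalala": 3102}
_FIXTURE_EXTERNAL = {
    "kilolo": ("KIL-HC02", "KIL-HC03", "KIL-H02", "KIL-H03"),
    "msalala": ("MSA-D25", "MSA-HC04", "MSA-H01", "MSA-H02"),
}
_FIXTURE_OWNERSHIP = {
    "kilolo": {"KIL-H01": "faith_based", "KIL-HC02": "faith_based",
               "KIL-HC03": "faith_based"},
    "msalala": {"MSA-HC04": "private", "MSA-H02": "faith_based"},
}


def _round_robin_pairs(senders: list[str], receivers: list[str],
                       count: int) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    used: set[tuple[str, str]] = set()
    t = 0
    while len(pairs) < count:
        if t > 100_000:
            raise ValidationError("cannot place requested flows on distinct dyads")
        s = senders[t % len(senders)]
        r = receivers[(t + t // len(senders)) % len(receivers)]
        t += 1
        if s == r or (s, r) in used:
            continue
        used.add((s, r))
        pairs.append((s, r))
    return pairs


def fixture_roster(district: str) -> Roster:
    """Deterministic fixture roster for one of the two study districts."""
    if district == "kilolo":
        config = kilolo_config()
    elif district == "msalala":
        config = msalala_config()
    else:
        raise ValidationError(f"unknown fixture district {district!r}")
    roster = generate_roster(config, seed=_FIXTURE_SEEDS[district])
    external = set(_FIXTURE_EXTERNAL[district])
    ownership = _FIXTURE_OWNERSHIP[district]
    adjusted = []
    for fac in roster:
        changes = {}
        if fac.facility_id in external:
            changes.update(surveyed=False, outpatient_visits_3m=None, rch_visits_3m=None)
        if fac.facility_id in ownership:
            changes["ownership"] = ownership[fac.facility_id]
        adjusted.append(dataclasses.replace(fac, **changes) if changes else fac)
    return Roster(adjusted)


def fixture_from_table4(district: str, domain: str) -> tuple[Roster, list[ReferralRecord]]:
    """Roster + records reproducing a published tier-to-tier breakdown.

    Edges are placed on distinct dyads by round-robin over facilities in
    roster order; the published table constrains only the tier-pair
    counts, so any such assignment is equally faithful.
    """
    if domain not in ("childcare", "ncd"):
        raise ValidationError(f"unknown domain {domain!r}")
    roster = fixture_roster(district)
    flows = _FLOWS[(district, domain)]
    by_tier = {tier: [f.facility_id for f in roster if f.tier == tier]
               for tier in ("dispensary", "health_centre", "hospital")}
    categories = _CATEGORIES[domain]
    records = []
    t = 0
    for (tier_s, tier_r), count in flows.items():
        for sender, receiver in _round_robin_pairs(by_tier[tier_s], by_tier[tier_r], count):
            records.append(ReferralRecord(
                sender_id=sender, receiver_id=receiver,
                condition_category=categories[t % len(categories)],
                domain=domain, n_referrals=1 + t % 3))
            t += 1
    return roster, records


def fixture_network(district: str, domain: str) -> ReferralNetwork:
    """Assembled fixture network (convenience wrapper)."""
    roster, records = fixture_from_table4(district, domain)
    return assemble_network(records, roster, district, domain)
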