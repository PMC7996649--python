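"""ERGM terms: sufficient statistics and change statistics.

An ERGM places probability ``P(Y = y) ∝ exp(θ·u(y))`` on directed binary
networks, where ``u(y)`` is a vector of sufficient statistics.  The term
vocabulary implemented here is exactly what the referral analysis needs:

``edges``
    Number of ties, Σ y_ij.
``isolates``
    Number of nodes with no incoming and no outgoing tie.
``gwidegree`` (decay α, fixed)
    Geometrically weighted in-degree distribution,
    e^α Σ_{k≥1} [1 − (1 − e^{−α})^k] D_k, where D_k is the number of
    nodes with in-degree k.  Penalizes concentration of incoming ties.
``edgecov`` (named dyadic covariate, e.g. road distance)
    Σ y_ij x_ij.
``node_cov_in / node_cov_out / node_cov_combined`` (numeric attribute)
    Σ y_ij a_j, Σ y_ij a_i, Σ y_ij (a_i + a_j), with the attribute passed
    through the term's transform (identity, log, log1p) first.
``node_factor_in / node_factor_combined`` (tier level)
    Indicator versions of the above for facility tiers; the reference
    level is ``dispensary`` and never appears as a term.

The change statistic δ_ij = u(y⁺ij) − u(y⁻ij) is computed incrementally
and, for every term, equals the global difference exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import DistanceMatrix, Roster, TIERS
from .network import ReferralNetwork

TERM_KINDS = (
    "edges", "isolates", "gwidegree", "edgecov",
    "node_factor_in", "node_cov_in", "node_cov_out",
    "node_cov_combined", "node_factor_combined",
)
TRANSFORMS = ("identity", "log", "log1p")
FACTOR_KINDS = ("node_factor_in", "node_factor_combined")
NODAL_KINDS = FACTOR_KINDS + ("node_cov_in", "node_cov_out", "node_cov_combined")

# integer codes for the numba sampler kernel
CODE_EDGES, CODE_ISOLATES, CODE_GWIDEG, CODE_DYADIC, CODE_NODAL = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class TermDef:
    """Declarative definition of one model term.

    ``decay`` is the fixed GWIDEG decay α (it is not estimated and not
    counted among the model's parameters beyond the coefficient itself).
    """

    kind: str
    attribute: str | None = None
    level: str | None = None
    transform: str = "identity"
    decay: float | None = None

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise ValidationError(f"unknown term kind {self.kind!r}")
        if self.transform not in TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.kind == "gwidegree":
            if self.decay is None or self.decay <= 0:
                raise ValidationError("gwidegree requires a positive fixed decay")
        elif self.decay is not None:
            raise ValidationError(f"decay is only valid for gwidegree, not {self.kind!r}")
        if self.kind in FACTOR_KINDS:
            if self.level is None:
                raise ValidationError(f"{self.kind} requires a factor level")
            if self.level not in TIERS:
                raise ValidationError(f"unknown tier level {self.level!r}")
            if self.level == "dispensary":
                raise ValidationError("dispensary is the factor reference level")
        if self.kind in ("edgecov", "node_cov_in", "node_cov_out", "node_cov_combined"):
            if self.attribute is None:
                raise ValidationError(f"{self.kind} requires an attribute name")

    @property
    def name(self) -> str:
        if self.kind == "edges" or self.kind == "isolates":
            return self.kind
        if self.kind == "gwidegree":
            return f"gwidegree({self.decay:g})"
        if self.kind in FACTOR_KINDS:
            return f"{self.kind}.{self.level}"
        label = self.attribute
        if self.transform != "identity":
            label = f"{self.transform}({label})"
        return f"{self.kind}.{label}"


def _apply_transform(values: np.ndarray, transform: str, label: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "log":
        if np.any(values <= 0):
            raise ValidationError(f"log transform of non-positive values in {label!r}")
        return np.log(values)
    return np.log1p(values)


class ErgmSpec:
    """Ordered term list bound to covariate sources.

    Parameters
    ----------
    terms
        Sequence of :class:`TermDef` (names must be unique).
    roster
        Facility roster supplying node covariates and tiers.
    distances
        Optional :class:`DistanceMatrix`; available to ``edgecov`` terms
        under the attribute name ``"distance"``.
    dyad_covariates
        Extra named dyadic matrices in roster order.
    """

    def __init__(self, terms, roster: Roster | None = None,
                 distances: DistanceMatrix | None = None,
                 dyad_covariates: dict[str, np.ndarray] | None = None):
        self.terms = list(terms)
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate term names in spec: {names}")
        self.roster = roster
        self.distances = distances
        self.dyad_covariates = dict(dyad_covariates or {})

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def k(self) -> int:
        return len(self.terms)

    def bind(self, net: ReferralNetwork, overrides: dict[str, dict[str, float]] | None = None
             ) -> "BoundSpec":
        """Resolve covariates against a network's node order.

        ``overrides`` maps facility_id -> {attribute: raw value} and is
        used by scenario prediction to perturb node attributes.
        """
        return BoundSpec(self, net, overrides or {})

    def _node_values(self, net: ReferralNetwork, attribute: str,
                     overrides: dict[str, dict[str, float]]) -> np.ndarray:
        if self.roster is None:
            raise ValidationError("spec has no roster; node covariates unavailable")
        out = np.empty(net.n)
        for pos, fid in enumerate(net.node_ids):
            fac = self.roster[fid]
            if attribute in overrides.get(fid, {}):
                value = overrides[fid][attribute]
            else:
                if not hasattr(fac, attribute):
                    raise ValidationError(f"unknown node attribute {attribute!r}")
                value = getattr(fac, attribute)
            if value is None:
                raise ValidationError(
                    f"missing covariate {attribute!r} for node {fid!r}")
            out[pos] = float(value)
        return out

    def _dyad_matrix(self, net: ReferralNetwork, attribute: str) -> np.ndarray:
        if attribute == "distance" and self.distances is not None:
            return self.distances.reorder(net.node_ids).values
        if attribute in self.dyad_covariates:
            if self.roster is None:
                raise ValidationError("dyadic covariates require a roster for ordering")
            full = np.asarray(self.dyad_covariates[attribute], dtype=float)
            idx = [self.roster.position(fid) for fid in net.node_ids]
            return full[np.ix_(idx, idx)]
        raise ValidationError(f"no dyadic covariate named {attribute!r}")


class BoundSpec:
    """Spec compiled against one network's node order.

    Produces the flat numeric arrays the sampler kernel consumes:
    integer term codes, GWIDEG decays, per-term sender/receiver nodal
    vectors and stacked dyadic covariate matrices.
    """

    def __init__(self, spec: ErgmSpec, net: ReferralNetwork,
                 overrides: dict[str, dict[str, float]]):
        self.spec = spec
        self.net = net
        n, k = net.n, spec.k
        self.codes = np.zeros(k, dtype=np.int64)
        self.alphas = np.zeros(k)
        self.snd = np.zeros((k, n))     # sender contribution per nodal term
        self.rcv = np.zeros((k, n))     # receiver contribution per nodal term
        self.dyad_index = np.full(k, -1, dtype=np.int64)
        dyad_mats = []

        tier_of = None
        if spec.roster is not None:
            tier_of = np.array([spec.roster[fid].tier for fid in net.node_ids])

        for t, term in enumerate(spec.terms):
            if term.kind == "edges":
                self.codes[t] = CODE_EDGES
            elif term.kind == "isolates":
                self.codes[t] = CODE_ISOLATES
            elif term.kind == "gwidegree":
                self.codes[t] = CODE_GWIDEG
                self.alphas[t] = term.decay
            elif term.kind == "edgecov":
                self.codes[t] = CODE_DYADIC
                mat = _apply_transform(spec._dyad_matrix(net, term.attribute),
                                       term.transform, term.attribute)
                self.dyad_index[t] = len(dyad_mats)
                dyad_mats.append(np.ascontiguousarray(mat, dtype=float))
            else:
                self.codes[t] = CODE_NODAL
                if term.kind in FACTOR_KINDS:
                    if tier_of is None:
                        raise ValidationError("factor terms require a roster")
                    values = (tier_of == term.level).astype(float)
                else:
                    values = _apply_transform(
                        spec._node_values(net, term.attribute, overrides),
                        term.transform, term.attribute)
                if term.kind in ("node_cov_in", "node_factor_in"):
                    self.rcv[t] = values
                elif term.kind == "node_cov_out":
                    self.snd[t] = values
                else:  # combined
                    self.snd[t] = values
                    self.rcv[t] = values

        self.dyad_mats = (np.stack(dyad_mats) if dyad_mats
                          else np.zeros((0, n, n)))

    @property
    def names(self) -> list[str]:
        return self.spec.names

    @property
    def k(self) -> int:
        return self.spec.k

    def statistics(self, adjacency: np.ndarray | None = None) -> np.ndarray:
        """Global statistic vector u(y)."""
        adj = self.net.adjacency if adjacency is None else np.asarray(adjacency)
        adjf = adj.astype(float)
        in_deg = adj.sum(axis=0).astype(np.int64)
        out_deg = adj.sum(axis=1).astype(np.int64)
        u = np.zeros(self.k)
        for t, term in enumerate(self.spec.terms):
            code = self.codes[t]
            if code == CODE_EDGES:
                u[t] = adj.sum()
            elif code == CODE_ISOLATES:
                u[t] = int(np.sum((in_deg + out_deg) == 0))
            elif code == CODE_GWIDEG:
                a = self.alphas[t]
                c = 1.0 - np.exp(-a)
                ks = in_deg[in_deg > 0]
                u[t] = np.exp(a) * np.sum(1.0 - c ** ks.astype(float))
            elif code == CODE_DYADIC:
                u[t] = float((adjf * self.dyad_mats[self.dyad_index[t]]).sum())
            else:
                u[t] = float(self.snd[t] @ out_deg + self.rcv[t] @ in_deg)
        return u

    def change_matrix(self, adjacency: np.ndarray | None = None) -> np.ndarray:
        """δ_ij for every dyad as an (n, n, k) array (diagonal is garbage).

        Each δ is evaluated on the network with the focal tie removed, so
        the conditional log-odds of tie (i, j) given the rest of the
        observed network is θ·δ_ij whether or not the tie is present.
        """
        adj = self.net.adjacency if adjacency is None else np.asarray(adjacency)
        n = adj.shape[0]
        adjf = adj.astype(float)
        in_deg = adj.sum(axis=0).astype(float)
        out_deg = adj.sum(axis=1).astype(float)
        deg = in_deg + out_deg
        delta = np.empty((n, n, self.k))
        for t in range(self.k):
            code = self.codes[t]
            if code == CODE_EDGES:
                delta[:, :, t] = 1.0
            elif code == CODE_ISOLATES:
                # degree of i and of j excluding the focal tie (i, j)
                deg_i = deg[:, None] - adjf
                deg_j = deg[None, :] - adjf
                delta[:, :, t] = -((deg_i == 0).astype(float) + (deg_j == 0).astype(float))
            elif code == CODE_GWIDEG:
                c = 1.0 - np.exp(-self.alphas[t])
                d_j = in_deg[None, :] - adjf
                delta[:, :, t] = c ** d_j
            elif code == CODE_DYADIC:
                delta[:, :, t] = self.dyad_mats[self.dyad_index[t]]
            else:
                delta[:, :, t] = self.snd[t][:, None] + self.rcv[t][None, :]
        return delta

    def change_statistic(self, i: int, j: int,
                         adjacency: np.ndarray | None = None) -> np.ndarray:
        """δ vector for a single dyad (i, j), focal tie excluded."""
        if i == j:
            raise ValidationError("change statistic undefined on the diagonal")
        return self.change_matrix(adjacency)[i, j]

    def dyads(self) -> tuple[np.ndarray, np.ndarray]:
        """Row-major off-diagonal dyad indices (deterministic roster order)."""
        n = self.net.n
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = ii != jj
        return ii[mask], jj[mask]


def network_statistics(net: ReferralNetwork, spec: ErgmSpec) -> np.ndarray:
    """Sufficient statistic vector u(y) of a network under a spec."""
    return spec.bind(net).statistics()


def change_statistics(net: ReferralNetwork, spec: ErgmSpec, dyad: tuple[int, int]) -> np.ndarray:
    """Change statistic vector δ_ij for one dyad of a network."""
    i, j = dyad
    return spec.bind(net).change_statistic(i, j)


def parse_term(text: str) -> TermDef:
    """Parse a compact term string as used by configs and the CLI.

    Examples: ``edges``, ``isolates``, ``gwidegree(0.7)``,
    ``edgecov(distance)``, ``edgecov(distance,log1p)``,
    ``node_cov_in(delivery_beds)``, ``node_cov_in(catchment_population,log)``,
    ``node_factor_in(hospital)``.
    """
    text = text.strip()
    if "(" not in text:
        return TermDef(kind=text)
    if not text.endswith(")"):
        raise ValidationError(f"malformed term {text!r}")
    kind, inner = text[:-1].split("(", 1)
    kind = kind.strip()
    args = [a.strip() for a in inner.split(",") if a.strip()]
    if kind == "gwidegree":
        if len(args) != 1:
            raise ValidationError(f"gwidegree takes a single decay: {text!r}")
        return TermDef(kind=kind, decay=float(args[0]))
    if kind in FACTOR_KINDS:
        level = args[0] if args else None
        return TermDef(kind=kind, attribute="tier", level=level)
    attribute = args[0] if args else None
    transform = args[1] if len(args) > 1 else "identity"
    return TermDef(kind=kind, attribute=attribute, transform=transform)


def parse_terms(text: str | list[str]) -> list[TermDef]:
    """Parse a ``+``-separated term list (or a list of term strings)."""
    if isinstance(text, str):
        parts = [p for p in (s.strip() for s in text.split("+")) if p]
    else:
        parts = list(text)
    return [parse_term(p) if isinstance(p, str) else p for p in parts]
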