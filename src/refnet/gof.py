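"""Goodness-of-fit by simulation, degeneracy diagnostics and tie-probability
scenario prediction.

GOF compares the observed network's monitored statistics — the model's
own sufficient statistics plus the full in- and out-degree distributions
— against 95% envelopes from networks simulated at the fitted
coefficients.  Degeneracy is flagged when the simulated density
collapses away from the observed one (mean below 0.1x or above 10x) or
the chain sticks at empty/complete graphs.

Tie probabilities are *conditional*: the change statistic δ_ij is
evaluated on the observed network with the focal tie absent, so
p_ij = logistic(θ·δ_ij) is the model's probability of the tie given the
rest of the network — the inverse-logit reading of ERGM coefficients.
In the edges-only model this reproduces the observed density for every
dyad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .ergm import ErgmResults, simulate_ergm


@dataclass(frozen=True)
class GofReport:
    """Observed vs simulated envelopes for each monitored statistic."""

    frame: pd.DataFrame        # statistic, observed, sim_mean, sim_p2.5, sim_p97.5, outside
    degenerate: bool
    n_sim: int
    seed: int

    @property
    def fraction_inside(self) -> float:
        return float(1.0 - self.frame["outside"].mean())

    def plot(self, ax=None):
        """Bar chart of observed statistics against simulation envelopes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(self.frame))))
        y = np.arange(len(self.frame))
        ax.hlines(y, self.frame["sim_p2.5"], self.frame["sim_p97.5"],
                  color="0.7", lw=4, label="95% envelope")
        ax.plot(self.frame["sim_mean"], y, "|", color="0.3", ms=10, label="sim mean")
        ax.plot(self.frame["observed"], y, "ko", ms=4, label="observed")
        ax.set_yticks(y, self.frame["statistic"], fontsize=6)
        ax.invert_yaxis()
        ax.legend(loc="best", fontsize=7)
        ax.set_title("Goodness of fit" + (" (DEGENERATE)" if self.degenerate else ""))
        return ax


@dataclass(frozen=True)
class TieProbability:
    """Conditional probability of one directed tie under a fitted model."""

    sender: str
    receiver: str
    linear_predictor: float
    probability: float


@dataclass(frozen=True)
class ScenarioResult:
    """Effect of an attribute change on one dyad's tie probability."""

    sender: str
    receiver: str
    p_old: float
    p_new: float
    lp_old: float
    lp_new: float

    @property
    def relative_change(self) -> float:
        return (self.p_new - self.p_old) / self.p_old


def _monitored(stats_names, net, adjacency=None):
    adj = net.adjacency if adjacency is None else adjacency
    in_deg = adj.sum(axis=0)
    out_deg = adj.sum(axis=1)
    n = adj.shape[0]
    in_dist = np.bincount(in_deg, minlength=n)[:n]
    out_dist = np.bincount(out_deg, minlength=n)[:n]
    return in_dist, out_dist


def gof_simulate(fit: ErgmResults, n_sim: int = 100, seed: int = 0,
                 burn_in: int = 20_000, interval: int = 200) -> GofReport:
    """Simulate at the fitted coefficients and envelope monitored statistics."""
    if n_sim < 10:
        raise ValidationError("gof requires n_sim >= 10")
    net = fit.model.network
    bound = fit.model.bound
    theta = fit.params.to_numpy()

    sims = simulate_ergm(net, fit.model.spec, theta, n_samples=n_sim,
                         burn_in=burn_in, interval=interval, seed=seed)

    names = list(fit.params.index)
    n = net.n
    rows_obs = np.concatenate([
        bound.statistics(),
        _monitored(names, net)[0],
        _monitored(names, net)[1],
    ])
    labels = (names + [f"in_degree_{k}" for k in range(n)]
              + [f"out_degree_{k}" for k in range(n)])

    sim_vals = np.empty((n_sim, len(labels)))
    densities = np.empty(n_sim)
    for s, sim in enumerate(sims):
        in_dist, out_dist = _monitored(names, net, sim.adjacency)
        sim_vals[s] = np.concatenate([bound.statistics(sim.adjacency),
                                      in_dist, out_dist])
        densities[s] = sim.n_edges / sim.n_dyads

    lo = np.percentile(sim_vals, 2.5, axis=0)
    hi = np.percentile(sim_vals, 97.5, axis=0)
    frame = pd.DataFrame({
        "statistic": labels,
        "observed": rows_obs,
        "sim_mean": sim_vals.mean(axis=0),
        "sim_p2.5": lo,
        "sim_p97.5": hi,
    })
    frame["outside"] = (frame["observed"] < frame["sim_p2.5"]) | \
                       (frame["observed"] > frame["sim_p97.5"])

    obs_density = net.n_edges / net.n_dyads
    mean_density = float(densities.mean())
    degenerate = False
    if obs_density > 0:
        degenerate = mean_density < 0.1 * obs_density or mean_density > 10 * obs_density
    at_boundary = np.mean((densities == 0.0) | (densities == 1.0))
    if at_boundary > 0.9:
        degenerate = True
    return GofReport(frame=frame, degenerate=bool(degenerate), n_sim=n_sim, seed=seed)


def tie_probability(fit: ErgmResults, dyad: tuple) -> TieProbability:
    """Conditional tie probability p_ij = inverse-logit(θ·δ_ij).

    ``dyad`` may be a pair of node positions or facility ids.  δ is
    computed on the observed network with the focal tie set absent.
    """
    net = fit.model.network
    i, j = _resolve_dyad(net, dyad)
    delta = fit.model.bound.change_statistic(i, j)
    lp = float(fit.params.to_numpy() @ delta)
    return TieProbability(sender=net.node_ids[i], receiver=net.node_ids[j],
                          linear_predictor=lp, probability=float(expit(lp)))


def scenario_delta(fit: ErgmResults, dyad: tuple,
                   receiver_changes: dict[str, float] | None = None,
                   sender_changes: dict[str, float] | None = None) -> ScenarioResult:
    """Relative tie-probability change under node-attribute modifications.

    ``receiver_changes`` / ``sender_changes`` map raw attribute names to
    *increments* (e.g. ``{"rooms": 5}`` for expanding from 40 to 45
    rooms).  Attributes not referenced by any model term trigger a
    warning and contribute nothing, so an irrelevant change yields a
    zero delta.  Changes are applied to the raw attribute before the
    term's transform.
    """
    receiver_changes = receiver_changes or {}
    sender_changes = sender_changes or {}
    net = fit.model.network
    spec = fit.model.spec
    i, j = _resolve_dyad(net, dyad)
    theta = fit.params.to_numpy()

    modeled = {t.attribute for t in spec.terms if t.attribute not in (None, "tier")}
    for attr in set(receiver_changes) | set(sender_changes):
        if attr not in modeled:
            warnings.warn(f"attribute {attr!r} is not in the model; "
                          "change has no effect", stacklevel=2)

    delta_old = fit.model.bound.change_statistic(i, j)
    lp_old = float(theta @ delta_old)

    overrides: dict[str, dict[str, float]] = {}
    roster = spec.roster
    for fid, changes in ((net.node_ids[j], receiver_changes),
                         (net.node_ids[i], sender_changes)):
        for attr, incr in changes.items():
            if attr not in modeled:
                continue
            base = getattr(roster[fid], attr)
            if base is None:
                raise ValidationError(f"missing covariate {attr!r} for node {fid!r}")
            overrides.setdefault(fid, {})[attr] = float(base) + float(incr)

    bound_new = spec.bind(net, overrides=overrides)
    delta_new = bound_new.change_statistic(i, j)
    lp_new = float(theta @ delta_new)
    return ScenarioResult(sender=net.node_ids[i], receiver=net.node_ids[j],
                          p_old=float(expit(lp_old)), p_new=float(expit(lp_new)),
                          lp_old=lp_old, lp_new=lp_new)


def _resolve_dyad(net, dyad) -> tuple[int, int]:
    i, j = dyad
    if isinstance(i, str):
        i = net.position(i)
    if isinstance(j, str):
        j = net.position(j)
    if i == j:
        raise ValidationError("dyad must be off-diagonal")
    return int(i), int(j)
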