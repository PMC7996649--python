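"""Directed ERGM estimation: maximum pseudolikelihood and MCMC-MLE.

The model is ``P(Y = y) = exp(θ·u(y)) / Z(θ)`` over simple directed
binary networks on a fixed node set.  Two estimators are provided, in a
statsmodels-like shape — build an :class:`Ergm` from a network and an
:class:`~refnet.terms.ErgmSpec`, call :meth:`Ergm.fit`, get an
:class:`ErgmResults`:

* **MPLE** maximizes the pseudolikelihood
  Σ_{i≠j} [y_ij θ·δ_ij − log(1 + exp(θ·δ_ij))] by Newton iteration with
  step-halving; this is logistic regression of tie indicators on change
  statistics, exact when terms are dyad-independent.
* **MCMC-MLE** refines the MPLE by Geyer–Thompson iteration: simulate
  networks at the current θ with the TNT sampler, maximize the
  importance-sampled log-likelihood-ratio approximation, repeat until
  the update is below tolerance.  Standard errors come from the inverse
  estimated Fisher information (the covariance of simulated
  statistics); the log-likelihood is estimated by a bridge/importance
  path from the null model θ = 0 (whose constant is m·log 2).

AIC = −2ℓ + 2k and BIC = −2ℓ + k·log m use m = n(n−1) directed dyads as
the sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .errors import DegeneracyError, QuasiSeparationWarning, SeparationError, ValidationError
from .network import ReferralNetwork
from .sampler import run_chain
from .terms import ErgmSpec


def information_criteria(loglik: float, k: int, m: int) -> tuple[float, float]:
    """AIC and BIC from log-likelihood, parameter count and dyad count."""
    if m < 1 or k < 0:
        raise ValidationError("information criteria require m >= 1 and k >= 0")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(m)
    return float(aic), float(bic)


@dataclass
class SamplerConfig:
    """Settings of one TNT sampling run (recorded with every fit)."""

    burn_in: int = 100_000
    interval: int = 1_000
    n_samples: int = 1_000
    seed: int = 0


class ErgmResults:
    """Fitted ERGM: coefficients, uncertainties, diagnostics.

    For MPLE fits ``llf`` is the maximized *pseudo*-log-likelihood and is
    labelled as such; information criteria across methods carry the
    method tag.
    """

    def __init__(self, model: "Ergm", params: np.ndarray, bse: np.ndarray,
                 llf: float | None, method: str, converged: bool,
                 cov_params: np.ndarray, sampler: SamplerConfig | None = None,
                 flags: dict | None = None):
        self.model = model
        self.params = pd.Series(params, index=model.spec.names, name="coef")
        self.bse = pd.Series(bse, index=model.spec.names, name="std err")
        self.llf = llf
        self.method = method
        self.converged = converged
        self._cov_params = cov_params
        self.sampler = sampler
        self.flags = flags or {}
        self.k = len(params)
        self.nobs = model.network.n_dyads
        if llf is not None:
            self.aic, self.bic = information_criteria(llf, self.k, self.nobs)
        else:
            self.aic = self.bic = None

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov_params, index=self.params.index,
                            columns=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self) -> str:
        net = self.model.network
        ll_label = "Pseudo-loglik" if self.method == "mple" else "Log-likelihood"
        lines = [
            "Exponential Random Graph Model".center(64),
            "=" * 64,
            f"District: {net.district:<22s} Domain: {net.domain}",
            f"Nodes: {net.n:<6d} Edges: {net.n_edges:<6d} Dyads: {self.nobs}",
            f"Method: {self.method:<12s} Converged: {self.converged}",
        ]
        if self.llf is not None:
            lines.append(f"{ll_label}: {self.llf:.2f}   AIC: {self.aic:.2f}   "
                         f"BIC: {self.bic:.2f}")
        decays = [t.decay for t in self.model.spec.terms if t.kind == "gwidegree"]
        if decays:
            lines.append("GWIDEG decay (fixed): " + ", ".join(f"{d:g}" for d in decays))
        lines.append("-" * 64)
        lines.append(f"{'term':<34s}{'coef':>10s}{'std err':>10s}{'z':>8s}")
        for name in self.params.index:
            z = self.params[name] / self.bse[name] if self.bse[name] > 0 else np.nan
            lines.append(f"{name:<34s}{self.params[name]:>10.3f}"
                         f"{self.bse[name]:>10.3f}{z:>8.2f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "converged": bool(self.converged),
            "coefficients": {n: float(v) for n, v in self.params.items()},
            "ses": {n: float(v) for n, v in self.bse.items()},
            "loglik": None if self.llf is None else float(self.llf),
            "loglik_kind": "pseudolikelihood" if self.method == "mple" else "mcmc",
            "k": int(self.k),
            "n_dyads": int(self.nobs),
            "aic": None if self.aic is None else float(self.aic),
            "bic": None if self.bic is None else float(self.bic),
            "decay": {t.name: float(t.decay) for t in self.model.spec.terms
                      if t.kind == "gwidegree"},
            "flags": self.flags,
        }
        if self.sampler is not None:
            out["sampler"] = {
                "burn_in": self.sampler.burn_in, "interval": self.sampler.interval,
                "n_samples": self.sampler.n_samples, "seed": self.sampler.seed,
            }
        return out

    # -- post-estimation ------------------------------------------------

    def simulate(self, n_samples: int = 100, burn_in: int | None = None,
                 interval: int | None = None, seed: int = 0,
                 init: str = "observed") -> list[ReferralNetwork]:
        """Draw networks from the fitted model (delegates to the sampler)."""
        if burn_in is None:
            burn_in = self.sampler.burn_in if self.sampler else 100_000
        if interval is None:
            interval = self.sampler.interval if self.sampler else 1_000
        return simulate_ergm(
            self.model.network, self.model.spec, self.params.to_numpy(),
            n_samples=n_samples, burn_in=burn_in, interval=interval,
            seed=seed, init=init)

    def gof(self, n_sim: int = 100, seed: int = 0, **kwargs):
        from .gof import gof_simulate
        return gof_simulate(self, n_sim=n_sim, seed=seed, **kwargs)

    def tie_probability(self, dyad: tuple):
        from .gof import tie_probability
        return tie_probability(self, dyad)

    def scenario_delta(self, dyad: tuple, receiver_changes: dict | None = None,
                       sender_changes: dict | None = None):
        from .gof import scenario_delta
        return scenario_delta(self, dyad, receiver_changes=receiver_changes,
                              sender_changes=sender_changes)


class Ergm:
    """ERGM of a referral network under a declared term set.

    Parameters
    ----------
    network
        Observed :class:`~refnet.network.ReferralNetwork`.
    spec
        :class:`~refnet.terms.ErgmSpec` with the ordered term list and
        covariate sources.
    """

    def __init__(self, network: ReferralNetwork, spec: ErgmSpec):
        self.network = network
        self.spec = spec
        self.bound = spec.bind(network)

    def at_params(self, theta) -> ErgmResults:
        """Results object at fixed (e.g. ground-truth) coefficients.

        No estimation is performed; useful for simulating or judging
        goodness of fit at known coefficients.
        """
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.spec.k,):
            raise ValidationError(
                f"expected {self.spec.k} coefficients, got {theta.shape}")
        k = len(theta)
        return ErgmResults(self, theta, np.zeros(k), None, method="fixed",
                           converged=True, cov_params=np.zeros((k, k)),
                           sampler=SamplerConfig())

    def fit(self, method: str = "mple", **kwargs) -> ErgmResults:
        """Estimate coefficients by ``"mple"`` or ``"mcmc"``."""
        if method == "mple":
            return self._fit_mple(**kwargs)
        if method in ("mcmc", "mcmc_mle"):
            return self._fit_mcmc(**kwargs)
        raise ValidationError(f"unknown estimation method {method!r}")

    # -- MPLE ------------------------------------------------------------

    def _pseudo_design(self) -> tuple[np.ndarray, np.ndarray]:
        ii, jj = self.bound.dyads()
        delta = self.bound.change_matrix()
        X = delta[ii, jj, :]
        y = self.network.adjacency[ii, jj].astype(float)
        return X, y

    def _fit_mple(self, ridge: float | None = None, max_iter: int = 100,
                  tol: float = 1e-10) -> ErgmResults:
        net = self.network
        if net.n_edges == 0:
            raise SeparationError("empty network: pseudolikelihood has no maximum")
        if net.n_edges == net.n_dyads:
            raise SeparationError("complete network: pseudolikelihood has no maximum")
        X, y = self._pseudo_design()
        pen = 0.0 if ridge is None else float(ridge)

        def objective(theta):
            eta = X @ theta
            return float(y @ eta - np.logaddexp(0.0, eta).sum()
                         - 0.5 * pen * theta @ theta)

        k = X.shape[1]
        theta = np.zeros(k)
        ll = objective(theta)
        for _ in range(max_iter):
            eta = X @ theta
            p = expit(eta)
            grad = X.T @ (y - p) - pen * theta
            w = p * (1.0 - p)
            hess = (X * w[:, None]).T @ X + pen * np.eye(k)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(hess + 1e-8 * np.eye(k), grad)
            # step-halving to guarantee ascent
            scale = 1.0
            for _ in range(40):
                cand = theta + scale * step
                ll_cand = objective(cand)
                if ll_cand >= ll - 1e-12:
                    break
                scale *= 0.5
            theta, ll_prev, ll = cand, ll, ll_cand
            if np.max(np.abs(grad)) < 1e-8 or abs(ll - ll_prev) < tol:
                break

        flags = {}
        if np.max(np.abs(theta)) > 20.0 and pen == 0.0:
            warnings.warn(
                "quasi-separation detected in MPLE (|coef| > 20); refitting "
                "with ridge penalty 1e-4", QuasiSeparationWarning, stacklevel=3)
            res = self._fit_mple(ridge=1e-4, max_iter=max_iter, tol=tol)
            res.flags["quasi_separation"] = True
            res.flags["ridge"] = 1e-4
            return res
        if pen > 0.0:
            flags["ridge"] = pen

        eta = X @ theta
        p = expit(eta)
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X + pen * np.eye(k)
        cov = np.linalg.pinv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        llf = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ErgmResults(self, theta, bse, llf, method="mple",
                           converged=True, cov_params=cov, flags=flags)

    # -- MCMC-MLE --------------------------------------------------------

    def _fit_mcmc(self, theta0: np.ndarray | None = None, n_samples: int = 1000,
                  burn_in: int = 100_000, interval: int = 1_000,
                  max_iter: int = 20, tol: float = 0.01, seed: int = 0,
                  estimate_loglik: bool = True, bridges: int = 16,
                  bridge_samples: int = 200, step_max: float = 1.0) -> ErgmResults:
        rng = np.random.default_rng(seed)
        if theta0 is None:
            start = self._fit_mple()
            theta = start.params.to_numpy()
            if start.flags.get("quasi_separation"):
                # a separated pseudolikelihood start parks the chain at
                # empty/complete graphs; restart from the edges-only fit
                # (which preserves the observed sparsity) and let partial
                # stepping walk the rest of the way
                net = self.network
                dens = net.n_edges / net.n_dyads
                theta = np.array([np.log(dens / (1.0 - dens))
                                  if term.kind == "edges" else 0.0
                                  for term in self.spec.terms])
        else:
            theta = np.asarray(theta0, dtype=float).copy()
        if not np.all(np.isfinite(theta)):
            raise ValidationError("non-finite starting coefficients")

        u_obs = self.bound.statistics()
        cfg = SamplerConfig(burn_in=burn_in, interval=interval,
                            n_samples=n_samples, seed=seed)
        converged = False
        flags = {}
        low_gamma = 0
        for _ in range(max_iter):
            chain_seed = int(rng.integers(2**31 - 1))
            stats, _ = run_chain(self.bound, theta, burn_in=burn_in,
                                 interval=interval, n_samples=n_samples,
                                 seed=chain_seed)
            # partial stepping: when u_obs sits outside the simulated
            # hull, aim at the nearest usable convex combination with the
            # simulated mean instead, and only count full-target
            # iterations toward convergence
            gamma = self._stepping_gamma(u_obs, stats)
            inside = bool(np.all((u_obs >= stats.min(axis=0))
                                 & (u_obs <= stats.max(axis=0))))
            if gamma < 0.05:
                low_gamma += 1
                if low_gamma >= 3:
                    self._raise_degenerate(u_obs, stats)
            else:
                low_gamma = 0
            target = gamma * u_obs + (1.0 - gamma) * stats.mean(axis=0)
            delta = self._geyer_thompson_step(theta, target, stats, step_max)
            theta = theta + delta
            # the update carries Monte-Carlo jitter of roughly one
            # coefficient standard error over sqrt(n_samples); stop once
            # the step is inside that noise floor (or below tol)
            cov_u = np.atleast_2d(np.cov(stats.T))
            noise = np.sqrt(np.clip(np.diag(np.linalg.pinv(cov_u)), 0.0, None)
                            / stats.shape[0])
            if inside and np.all(np.abs(delta) <= np.maximum(tol, 3.0 * noise)):
                converged = True
                break

        # Fisher information = Var_theta(u); final sample at the estimate
        chain_seed = int(rng.integers(2**31 - 1))
        stats, _ = run_chain(self.bound, theta, burn_in=burn_in,
                             interval=interval, n_samples=n_samples,
                             seed=chain_seed)
        if not np.all((u_obs >= stats.min(axis=0)) & (u_obs <= stats.max(axis=0))):
            converged = False
            flags["hull_warning"] = True
        cov_u = np.atleast_2d(np.cov(stats.T))
        cov = np.linalg.pinv(cov_u)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        llf = None
        if estimate_loglik:
            llf = self._bridge_loglik(theta, u_obs, rng, bridges, bridge_samples)
        return ErgmResults(self, theta, bse, llf, method="mcmc_mle",
                           converged=converged, cov_params=cov, sampler=cfg,
                           flags=flags)

    @staticmethod
    def _stepping_gamma(u_obs: np.ndarray, stats: np.ndarray) -> float:
        """Largest γ ∈ [0, 1] with γ·u_obs + (1−γ)·ū inside the sampled box.

        Componentwise approximation of the convex-hull condition, with a
        5% interior margin so importance weights stay stable.
        """
        lo = stats.min(axis=0)
        hi = stats.max(axis=0)
        span = np.maximum(hi - lo, 1e-8)
        lo_adj = lo + 0.05 * span
        hi_adj = hi - 0.05 * span
        mean = stats.mean(axis=0)
        gamma = 1.0
        for c in range(stats.shape[1]):
            diff = u_obs[c] - mean[c]
            if diff > 1e-12:
                gamma = min(gamma, (hi_adj[c] - mean[c]) / diff)
            elif diff < -1e-12:
                gamma = min(gamma, (lo_adj[c] - mean[c]) / diff)
        return float(max(gamma, 0.0))

    def _raise_degenerate(self, u_obs: np.ndarray, stats: np.ndarray) -> None:
        lo = stats.min(axis=0)
        hi = stats.max(axis=0)
        outside = (u_obs < lo) | (u_obs > hi)
        names = np.asarray(self.spec.names)[outside].tolist() or self.spec.names
        raise DegeneracyError(
            "observed statistics remain outside the simulated convex hull for "
            f"{names}; the model is degenerate at the current coefficients",
            payload={
                "observed": dict(zip(self.spec.names, u_obs.tolist())),
                "simulated_min": dict(zip(self.spec.names, lo.tolist())),
                "simulated_max": dict(zip(self.spec.names, hi.tolist())),
                "simulated_mean": dict(zip(self.spec.names,
                                           stats.mean(axis=0).tolist())),
            })

    @staticmethod
    def _geyer_thompson_step(theta: np.ndarray, u_obs: np.ndarray,
                             stats: np.ndarray, step_max: float) -> np.ndarray:
        """Maximize the importance-sampled log-likelihood ratio in Δθ.

        ψ(Δ) = Δ·u_obs − log mean exp(Δ·u_s) is concave; Newton iterate
        with the step capped so importance weights stay usable.
        """
        k = theta.shape[0]
        delta = np.zeros(k)
        for _ in range(50):
            logw = stats @ delta
            logw -= logsumexp(logw)
            w = np.exp(logw)
            mean_u = w @ stats
            cov_u = np.atleast_2d(np.cov(stats.T, aweights=w, ddof=0))
            grad = u_obs - mean_u
            try:
                step = np.linalg.solve(cov_u + 1e-10 * np.eye(k), grad)
            except np.linalg.LinAlgError:
                step = grad
            norm = np.max(np.abs(step))
            if norm > 0.25:
                step *= 0.25 / norm
            delta = delta + step
            if np.max(np.abs(delta)) > step_max:
                delta *= step_max / np.max(np.abs(delta))
                break
            if norm < 1e-6:
                break
        return delta

    def _bridge_loglik(self, theta: np.ndarray, u_obs: np.ndarray,
                       rng: np.random.Generator, bridges: int,
                       bridge_samples: int) -> float:
        """ℓ(θ̂) via a bridge/importance path from a tractable reference.

        The reference keeps θ̂ on the dyad-independent terms (edges,
        covariate terms — their normalizer factorizes over dyads and is
        computed exactly) and zeroes the dyad-dependent ones (isolates,
        gwidegree).  Each bridge then only spans the dyad-dependent
        coordinates, whose statistics have small spread, so the
        importance estimates of log Z(t+1) − log Z(t) are stable.
        """
        from .terms import CODE_GWIDEG, CODE_ISOLATES

        dep = np.isin(self.bound.codes, (CODE_ISOLATES, CODE_GWIDEG))
        theta_ref = np.where(dep, 0.0, theta)

        # exact normalizer of the dyad-independent reference
        ii, jj = self.bound.dyads()
        zero = np.zeros_like(self.network.adjacency)
        c = self.bound.change_matrix(zero)[ii, jj, :]  # constants for indep terms
        lp_ref = c @ theta_ref
        log_z = float(np.logaddexp(0.0, lp_ref).sum())

        direction = theta - theta_ref
        if np.any(dep):
            ts = np.linspace(0.0, 1.0, bridges + 1)
            for t0, t1 in zip(ts[:-1], ts[1:]):
                chain_seed = int(rng.integers(2**31 - 1))
                stats, _ = run_chain(self.bound, theta_ref + t0 * direction,
                                     burn_in=20_000, interval=100,
                                     n_samples=bridge_samples, seed=chain_seed)
                incr = (t1 - t0) * (stats @ direction)
                log_z += float(logsumexp(incr) - np.log(len(incr)))
        return float(theta @ u_obs - log_z)


# ---------------------------------------------------------------------------
# functional front doors


def mple(net: ReferralNetwork, spec: ErgmSpec, **kwargs) -> ErgmResults:
    """Maximum pseudolikelihood fit (see :class:`Ergm`)."""
    return Ergm(net, spec).fit(method="mple", **kwargs)


def mcmc_mle(net: ReferralNetwork, spec: ErgmSpec, **kwargs) -> ErgmResults:
    """MCMC maximum-likelihood fit (see :class:`Ergm`)."""
    return Ergm(net, spec).fit(method="mcmc", **kwargs)


def simulate_ergm(net: ReferralNetwork, spec: ErgmSpec, theta, *,
                  n_samples: int = 100, burn_in: int = 100_000,
                  interval: int = 1_000, seed: int = 0,
                  init: str = "observed") -> list[ReferralNetwork]:
    """Draw networks from an ERGM at fixed coefficients.

    ``init`` chooses the chain's starting state: the observed network
    (``"observed"``) or the empty graph (``"empty"``).
    """
    bound = spec.bind(net)
    start = None if init == "observed" else np.zeros_like(net.adjacency)
    _, nets = run_chain(bound, theta, burn_in=burn_in, interval=interval,
                        n_samples=n_samples, seed=seed, init=start,
                        keep_nets=True)
    return [net.with_adjacency(nets[s]) for s in range(nets.shape[0])]


def simulate_statistics(net: ReferralNetwork, spec: ErgmSpec, theta, *,
                        n_samples: int = 100, burn_in: int = 100_000,
                        interval: int = 1_000, seed: int = 0,
                        init: str = "observed") -> np.ndarray:
    """Sampled sufficient-statistic vectors, without storing networks."""
    bound = spec.bind(net)
    start = None if init == "observed" else np.zeros_like(net.adjacency)
    stats, _ = run_chain(bound, theta, burn_in=burn_in, interval=interval,
                         n_samples=n_samples, seed=seed, init=start)
    return stats
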