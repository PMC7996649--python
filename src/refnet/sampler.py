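"""Tie/no-tie (TNT) Metropolis–Hastings sampler for directed ERGMs.

The proposal alternates (prob. 1/2 each, once any tie exists) between
toggling off a uniformly chosen existing tie and toggling a uniformly
chosen dyad; the acceptance ratio carries the exact proposal correction,
so the chain is in detailed balance with P(y) ∝ exp(θ·u(y)).  TNT mixes
far better than pure dyad toggling on the very sparse networks referral
systems produce.

The hot loop is JIT-compiled with numba; statistics are maintained
incrementally from change statistics, which the test suite verifies
against global recomputation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .terms import CODE_DYADIC, CODE_EDGES, CODE_GWIDEG, CODE_ISOLATES


@njit(cache=True)
def _delta_into(out, i, j, present, in_deg, out_deg, codes, alphas, snd, rcv,
                dyad_mats, dyad_index):
    # δ = u(y with tie ij) − u(y without tie ij); focal tie excluded from degrees
    for t in range(codes.shape[0]):
        code = codes[t]
        if code == CODE_EDGES:
            out[t] = 1.0
        elif code == CODE_ISOLATES:
            di = in_deg[i] + out_deg[i] - present
            dj = in_deg[j] + out_deg[j] - present
            val = 0.0
            if di == 0:
                val -= 1.0
            if dj == 0:
                val -= 1.0
            out[t] = val
        elif code == CODE_GWIDEG:
            c = 1.0 - np.exp(-alphas[t])
            dj = in_deg[j] - present
            out[t] = c ** dj
        elif code == CODE_DYADIC:
            out[t] = dyad_mats[dyad_index[t], i, j]
        else:
            out[t] = snd[t, i] + rcv[t, j]


@njit(cache=True)
def _tnt_chain(adj, theta, codes, alphas, snd, rcv, dyad_mats, dyad_index, u0,
               burn_in, interval, n_samples, seed, keep_nets):
    np.random.seed(seed)
    n = adj.shape[0]
    m = n * (n - 1)
    k = theta.shape[0]

    # edge list with O(1) deletion via a position index
    edge_i = np.empty(m, np.int64)
    edge_j = np.empty(m, np.int64)
    edge_pos = np.full((n, n), -1, np.int64)
    in_deg = np.zeros(n, np.int64)
    out_deg = np.zeros(n, np.int64)
    ne = 0
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j] != 0:
                edge_i[ne] = i
                edge_j[ne] = j
                edge_pos[i, j] = ne
                ne += 1
                out_deg[i] += 1
                in_deg[j] += 1

    u = u0.copy()
    d = np.empty(k)
    stats = np.empty((n_samples, k))
    nets = np.empty((n_samples if keep_nets else 0, n, n), np.uint8)

    total = burn_in + n_samples * interval
    s_idx = 0
    for step in range(total):
        if ne > 0 and np.random.random() < 0.5:
            e = np.random.randint(0, ne)
            i = edge_i[e]
            j = edge_j[e]
        else:
            i = np.random.randint(0, n)
            j = np.random.randint(0, n - 1)
            if j >= i:
                j += 1
        present = np.int64(adj[i, j])
        _delta_into(d, i, j, present, in_deg, out_deg, codes, alphas, snd, rcv,
                    dyad_mats, dyad_index)
        lp = 0.0
        for t in range(k):
            lp += theta[t] * d[t]
        if present == 1:
            # toggle off; forward can come from either branch
            p_fwd = 0.5 / ne + 0.5 / m
            p_back = 0.5 / m if ne - 1 > 0 else 1.0 / m
            log_ratio = -lp + np.log(p_back) - np.log(p_fwd)
        else:
            p_fwd = 0.5 / m if ne > 0 else 1.0 / m
            p_back = 0.5 / (ne + 1) + 0.5 / m
            log_ratio = lp + np.log(p_back) - np.log(p_fwd)
        if np.log(np.random.random()) < log_ratio:
            if present == 1:
                adj[i, j] = 0
                e = edge_pos[i, j]
                last = ne - 1
                edge_i[e] = edge_i[last]
                edge_j[e] = edge_j[last]
                edge_pos[edge_i[e], edge_j[e]] = e
                edge_pos[i, j] = -1
                ne -= 1
                out_deg[i] -= 1
                in_deg[j] -= 1
                for t in range(k):
                    u[t] -= d[t]
            else:
                adj[i, j] = 1
                edge_i[ne] = i
                edge_j[ne] = j
                edge_pos[i, j] = ne
                ne += 1
                out_deg[i] += 1
                in_deg[j] += 1
                for t in range(k):
                    u[t] += d[t]
        if step >= burn_in and (step - burn_in + 1) % interval == 0:
            for t in range(k):
                stats[s_idx, t] = u[t]
            if keep_nets:
                for a in range(n):
                    for b in range(n):
                        nets[s_idx, a, b] = adj[a, b]
            s_idx += 1
    return stats, nets


def run_chain(bound, theta, *, burn_in: int, interval: int, n_samples: int,
              seed: int, init: np.ndarray | None = None, keep_nets: bool = False):
    """Run a TNT chain for a bound spec; returns (stats, nets) arrays.

    ``stats`` is (n_samples, k); ``nets`` is (n_samples, n, n) uint8 when
    ``keep_nets`` else empty.  Fully reproducible from ``seed``.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite coefficients passed to the sampler")
    if burn_in < 0 or interval < 1 or n_samples < 1:
        raise ValueError("sampler config requires burn_in >= 0, interval >= 1, n_samples >= 1")
    adj = (bound.net.adjacency.copy() if init is None
           else np.ascontiguousarray(init, dtype=np.uint8).copy())
    u0 = bound.statistics(adj)
    # numba's legacy RNG seed must fit in uint32
    seed = int(seed) % (2**31 - 1)
    return _tnt_chain(
        adj, theta, bound.codes, bound.alphas,
        np.ascontiguousarray(bound.snd), np.ascontiguousarray(bound.rcv),
        np.ascontiguousarray(bound.dyad_mats), bound.dyad_index, u0,
        int(burn_in), int(interval), int(n_samples), seed, keep_nets,
    )
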