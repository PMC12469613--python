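"""Metropolis kernel over stage-cluster assignments (numba-compiled hot loop).

Each iteration re-evaluates the full observed-data likelihood for the
perturbed subtype's assignment vector — an O(N*S*M) dense evaluation — so the
sampler's cost structure mirrors the E-step's.  The kernel is jitted because
the surrounding loop runs for 10^4-10^5 iterations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mcmc_orderings"]

_NEG_INF = -np.inf


@njit(cache=True)
def _total_loglik(D, pre_tot, rest, z, S, log_pi_k, L, zb):
    """Sum over subjects of log( exp(rest_n) + pi_k/(S+1) * sum_s L(x_n|k,s) ).

    The stage likelihoods accumulate per (subject, stage, biomarker) — the
    O(N*S*M) evaluation the model's complexity analysis is built on.  ``L``
    is an (N, S+1) workspace whose first column must stay zero; ``zb`` is an
    (S+1, M) workspace for the event-passed indicators.
    """
    N, M = D.shape
    for s in range(1, S + 1):
        for m in range(M):
            zb[s, m] = 1.0 if z[m] < s else 0.0
    for n in range(N):
        for s in range(1, S + 1):
            acc = 0.0
            for m in range(M):
                acc += D[n, m] * zb[s, m]
            L[n, s] = acc
    log_stage_prior = -np.log(S + 1.0)
    total = 0.0
    for n in range(N):
        mx = L[n, 0]
        for s in range(1, S + 1):
            if L[n, s] > mx:
                mx = L[n, s]
        acc = 0.0
        for s in range(S + 1):
            v = L[n, s] - mx
            if v > -37.0:             # exp(v) below double-precision eps
                acc += np.exp(v)
        contrib = pre_tot[n] + log_pi_k + log_stage_prior + mx + np.log(acc)
        r = rest[n]
        if r == _NEG_INF:
            total += contrib
        elif contrib >= r:
            total += contrib + np.log1p(np.exp(r - contrib))
        else:
            total += r + np.log1p(np.exp(contrib - r))
    return total


@njit(cache=True)
def _pick_member(z, c, count_c):
    """Uniformly chosen biomarker index currently in cluster c."""
    j = np.random.randint(count_c)
    seen = 0
    for m in range(len(z)):
        if z[m] == c:
            if seen == j:
                return m
            seen += 1
    return -1


@njit(cache=True)
def _kernel(D, pre_tot, rest, z, S, min_cluster, n_burn, n_final, log_pi_k, seed):
    np.random.seed(seed)
    N, M = D.shape
    counts = np.zeros(S, dtype=np.int64)
    for m in range(M):
        counts[z[m]] += 1
    L = np.zeros((N, S + 1))
    zb = np.zeros((S + 1, M))
    cur_ll = _total_loglik(D, pre_tot, rest, z, S, log_pi_k, L, zb)
    best_ll = cur_ll
    best_z = z.copy()
    occupancy = np.zeros((M, S))
    n_accept = 0
    if S < 2:
        for m in range(M):
            occupancy[m, 0] = n_final
        return occupancy, best_z, best_ll, n_accept
    for it in range(n_burn + n_final):
        do_move = np.random.random() < 0.5
        if do_move:
            m = np.random.randint(M)
            c = z[m]
            if np.random.random() < 0.5:
                t = c + 1
            else:
                t = c - 1
            if 0 <= t < S and counts[c] > min_cluster:
                z[m] = t
                new_ll = _total_loglik(D, pre_tot, rest, z, S, log_pi_k, L, zb)
                if np.log(np.random.random()) < new_ll - cur_ll:
                    counts[c] -= 1
                    counts[t] += 1
                    cur_ll = new_ll
                    n_accept += 1
                    if cur_ll > best_ll:
                        best_ll = cur_ll
                        best_z = z.copy()
                else:
                    z[m] = c
        else:
            b = np.random.randint(S - 1)
            m1 = _pick_member(z, b, counts[b])
            m2 = _pick_member(z, b + 1, counts[b + 1])
            z[m1] = b + 1
            z[m2] = b
            new_ll = _total_loglik(D, pre_tot, rest, z, S, log_pi_k, L, zb)
            if np.log(np.random.random()) < new_ll - cur_ll:
                cur_ll = new_ll
                n_accept += 1
                if cur_ll > best_ll:
                    best_ll = cur_ll
                    best_z = z.copy()
            else:
                z[m1] = b
                z[m2] = b + 1
        if it >= n_burn:
            for m in range(M):
                occupancy[m, z[m]] += 1.0
    return occupancy, best_z, best_ll, n_accept


def mcmc_orderings(
    D: np.ndarray,
    pre_tot: np.ndarray,
    rest: np.ndarray,
    z0: np.ndarray,
    n_stages: int,
    min_cluster: int,
    n_burn: int,
    n_final: int,
    log_pi_k: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Run the Metropolis sampler for one subtype.

    Parameters are the cached per-biomarker log-density ratio ``D``
    (log post - log pre, N x M), the per-subject total pre-event log density,
    the other subtypes' per-subject log contribution (``-inf`` when K = 1),
    and the subtype's starting cluster assignment.  Returns the retained
    occupancy counts (M x S), the best sampled assignment, its total
    log-likelihood and the accepted-proposal count.
    """
    occupancy, best_z, best_ll, n_accept = _kernel(
        np.ascontiguousarray(D, dtype=np.float64),
        np.ascontiguousarray(pre_tot, dtype=np.float64),
        np.ascontiguousarray(rest, dtype=np.float64),
        np.ascontiguousarray(z0, dtype=np.int64),
        int(n_stages), int(min_cluster), int(n_burn), int(n_final),
        float(log_pi_k), int(seed),
    )
    return occupancy, best_z, float(best_ll), int(n_accept)
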