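"""Exact transition-probability oracle for tiny simulations.

Independent re-derivation of the two-phase monthly update from its stated
rules: for n <= 3 agents, enumerate every within-phase permutation and every
branch of the sequential Bernoulli updates to obtain the exact distribution
over state vectors after T steps. Used to validate the compiled simulation
kernel by comparing Monte Carlo frequencies with exact probabilities.
"""

from itertools import permutations

import numpy as np


def _clip(x):
    return min(max(x, 0.0), 1.0)


def _phase(states_probs, adj, update_one, n):
    """Apply one phase: average over agent-visit permutations of the
    sequential branching update."""
    out = {}
    perms = list(permutations(range(n)))
    for state, prob in states_probs.items():
        for perm in perms:
            # each permutation contributes prob / n!
            branches = {state: prob / len(perms)}
            for i in perm:
                nxt = {}
                for s, p in branches.items():
                    for s2, p2 in update_one(s, i, adj):
                        nxt[s2] = nxt.get(s2, 0.0) + p * p2
                branches = nxt
            for s, p in branches.items():
                out[s] = out.get(s, 0.0) + p
    return out


def exact_distribution(adj, aware_base, adopt_base, omega_a, beta_s, tau, T):
    """Exact distribution over final state vectors (tuples in {0,1,2}^n)
    after T two-phase steps under the clipped-linear link.

    ``adj`` is a list of neighbor lists; ``aware_base``/``adopt_base`` the
    per-agent linear-predictor constants (background+media, scaled baseline
    hazard+media).
    """
    n = len(adj)
    assert n <= 3, "exact enumeration is intended for n <= 3"

    def update_aware(state, i, adj):
        if state[i] != 0:
            return [(state, 1.0)]
        nbrs = adj[i]
        frac = (sum(state[j] >= 1 for j in nbrs) / len(nbrs)) if nbrs else 0.0
        p = _clip(aware_base[i] + omega_a * frac)
        s_new = tuple(1 if k == i else v for k, v in enumerate(state))
        return [(s_new, p), (state, 1.0 - p)] if p > 0 else [(state, 1.0)]

    def update_adopt(state, i, adj):
        if state[i] != 1:
            return [(state, 1.0)]
        nbrs = adj[i]
        nad = sum(state[j] == 2 for j in nbrs)
        frac = nad / len(nbrs) if nbrs else 0.0
        p = _clip(adopt_base[i] + (beta_s * frac if nad >= tau else 0.0))
        s_new = tuple(2 if k == i else v for k, v in enumerate(state))
        return [(s_new, p), (state, 1.0 - p)] if p > 0 else [(state, 1.0)]

    dist = {tuple([0] * n): 1.0}
    for _ in range(T):
        dist = _phase(dist, adj, update_aware, n)
        dist = _phase(dist, adj, update_adopt, n)
    return dist


def exact_adoption_pmf(dist, n):
    """P(number of adopters = k) from a state-vector distribution."""
    pmf = np.zeros(n + 1)
    for state, p in dist.items():
        pmf[sum(v == 2 for v in state)] += p
    return pmf
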