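"""Shared fixtures and independent oracles.

The brute-force likelihood oracles here enumerate internal-state
assignments explicitly (vectorized over the enumeration, never recursing
over the tree), so they are independent of the pruning implementation they
check.
"""

import numpy as np
import pytest

from opsinphylo.phylo_core import MISSING


def brute_force_site_logliks(tree, tip_codes, P_stacks, prior, weights):
    """Per-site log-likelihood by explicit enumeration of internal states.

    P_stacks: dict id(node) -> (C, k, k) transition matrices for the branch
    above the node. prior: (k,). weights: (C,).
    """
    internals = [n for n in tree.postorder() if not n.is_tip]
    prior = np.asarray(prior, dtype=float)
    k = len(prior)
    m = len(internals)
    idx = {id(n): i for i, n in enumerate(internals)}
    grids = np.indices((k,) * m).reshape(m, -1)  # (m, k^m)
    n_sites = len(next(iter(tip_codes.values())))
    C = len(weights)
    out = np.empty(n_sites)
    for s in range(n_sites):
        mix = 0.0
        for c in range(C):
            val = prior[grids[idx[id(tree.root)]]].astype(float)
            for node in tree.branches():
                P = P_stacks[id(node)][c]
                parent_states = grids[idx[id(node.parent)]]
                if node.is_tip:
                    code = tip_codes[node.label][s]
                    if code != MISSING:
                        val = val * P[parent_states, code]
                else:
                    val = val * P[parent_states, grids[idx[id(node)]]]
            mix += weights[c] * val.sum()
        out[s] = np.log(mix)
    return out


def brute_force_marginals(tree, tip_codes, P_single, prior, site=0):
    """Marginal internal-state probabilities by Bayes rule over the same
    enumeration: P(state_v = a | data) for every internal node v."""
    internals = [n for n in tree.postorder() if not n.is_tip]
    prior = np.asarray(prior, dtype=float)
    k = len(prior)
    m = len(internals)
    idx = {id(n): i for i, n in enumerate(internals)}
    grids = np.indices((k,) * m).reshape(m, -1)
    val = prior[grids[idx[id(tree.root)]]].astype(float)
    for node in tree.branches():
        P = P_single[id(node)]
        parent_states = grids[idx[id(node.parent)]]
        if node.is_tip:
            code = tip_codes[node.label][site]
            if code != MISSING:
                val = val * P[parent_states, code]
        else:
            val = val * P[parent_states, grids[idx[id(node)]]]
    total = val.sum()
    marginals = {}
    for node in internals:
        row = np.array([val[grids[idx[id(node)]] == a].sum() for a in range(k)])
        marginals[id(node)] = row / total
    return marginals


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
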