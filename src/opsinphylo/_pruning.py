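"""Shared Felsenstein-pruning engine.

Computes per-site log-likelihoods on a rooted tree for an arbitrary
reversible (or not) finite-state model, optionally as a mixture over site
classes that share the topology and branch lengths but differ in their
transition matrices. Per-node, per-site rescaling keeps partial likelihoods
in range for deep trees.

Tip data are integer state codes with ``MISSING`` (= -1) contributing a
partial likelihood of 1 in every state.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .phylo_core import MISSING, Tree

__all__ = ["mixture_site_loglik", "class_site_loglik"]


def class_site_loglik(tree: Tree, tip_codes: dict[str, np.ndarray],
                      P_of, root_prior: np.ndarray) -> np.ndarray:
    """Per-class, per-site log-likelihood matrix (n_classes, n_sites).

    Parameters
    ----------
    tip_codes
        tip label -> (n_sites,) integer state codes (MISSING allowed).
    P_of
        callable(node) -> (n_classes, k, k) stack of transition matrices
        for the branch above ``node``.
    root_prior
        (k,) state distribution at the root (shared across classes) or
        (n_classes, k).
    """
    labels = set(tip_codes)
    tree.check_tip_coverage(labels)
    tips = set(tree.tip_labels)
    extra = tips - labels
    if extra:
        raise ValueError(f"tree tips without data: {sorted(extra)}")

    some = next(iter(tip_codes.values()))
    n_sites = len(some)
    probe = P_of(tree.branches()[0])
    n_classes, k, _ = probe.shape

    partial = {}
    logscale = {}
    for node in tree.postorder():
        if node.is_tip:
            continue
        acc = np.ones((n_classes, n_sites, k))
        scale = np.zeros((n_classes, n_sites))
        for child in node.children:
            P = P_of(child)  # (C, k, k)
            if child.is_tip:
                codes = np.asarray(tip_codes[child.label])
                contrib = np.where(
                    codes[None, None, :] == MISSING,
                    1.0,
                    P[:, :, np.where(codes == MISSING, 0, codes)],
                )  # (C, k, n_sites)
                contrib = np.swapaxes(contrib, 1, 2)  # (C, n_sites, k)
            else:
                contrib = np.matmul(partial.pop(id(child)),
                                    np.swapaxes(P, 1, 2))
                scale += logscale.pop(id(child))
            acc = acc * contrib
        m = acc.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        acc /= m[:, :, None]
        scale += np.log(m)
        partial[id(node)] = acc
        logscale[id(node)] = scale

    root = partial[id(tree.root)]
    prior = np.asarray(root_prior, dtype=float)
    if prior.ndim == 1:
        prior = np.broadcast_to(prior, (n_classes, k))
    site_lik = np.einsum("csk,ck->cs", root, prior)
    with np.errstate(divide="ignore"):
        return np.log(site_lik) + logscale[id(tree.root)]


def mixture_site_loglik(tree, tip_codes, P_of, root_prior,
                        class_weights) -> tuple[np.ndarray, np.ndarray]:
    """Mixture per-site log-likelihoods and the per-class matrix.

    Returns ``(site_loglik, class_loglik)`` where
    ``site_loglik[s] = log sum_c w_c exp(class_loglik[c, s])``.
    """
    class_ll = class_site_loglik(tree, tip_codes, P_of, root_prior)
    w = np.asarray(class_weights, dtype=float)
    if w.ndim != 1 or len(w) != class_ll.shape[0]:
        raise ValueError("class weight vector does not match class count")
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    site_ll = logsumexp(class_ll + logw[:, None], axis=0)
    return site_ll, class_ll
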