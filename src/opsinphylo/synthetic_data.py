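"""Generators for trees, codon alignments and trait data, plus static
fixtures transcribed from printed results.

The generators close the simulate-then-fit loop for every model family in
the package: codon alignments are evolved under the same GY94 mixture (or
per-branch omega map) and the same generator scaling that the fitters
assume, discrete traits under Mk chains, continuous traits under Brownian
motion. Every generator is bit-reproducible given a seed.

Codon simulation samples codon states directly from branch transition
probabilities at branch ends (not by Gillespie waiting times); per-branch
substitution bookkeeping, where needed, is computed analytically from the
model, which is sufficient for the recovery tests the generators feed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_selection import _CodonLikelihood, _SpectralQ, discretize_beta
from .phylo_core import (
    CODONS,
    CodonAlignment,
    Tree,
    TreeNode,
    ValidationError,
)
from .trait_reconstruction import MkModel

N_CODONS = 61


@dataclass
class SimulationConfig:
    """Bundle of generator settings for a full synthetic scenario."""

    n_tips: int = 12
    birth_rate: float = 1.0
    tree_newick: str | None = None
    n_codon_sites: int = 300
    kappa: float = 2.0
    site_model: str = "M7"          # M7 | M8 | one_ratio | branch_map
    beta_p: float = 0.5
    beta_q: float = 1.5
    p1: float = 0.15
    omega_s: float = 4.0
    omega: float = 0.2
    branch_omegas: dict = field(default_factory=dict)
    K: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("birth_rate", "kappa", "beta_p", "beta_q", "omega_s", "omega"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Trees


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Tree:
    """Ultrametric pure-birth (Yule) tree with exactly ``n_tips`` tips.

    Lineages split one at a time at exponential waiting times with total
    rate ``birth_rate * k``; all surviving lineages are extended to the
    present. Tips are labelled t1..tn in order of creation.
    """
    if n_tips < 2:
        raise ValidationError("need at least two tips")
    if birth_rate <= 0:
        raise ValidationError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    root = TreeNode(None, 0.0)
    a = root.add_child(TreeNode("t1", 0.0))
    b = root.add_child(TreeNode("t2", 0.0))
    active = [a, b]
    label = 3
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += dt
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        parent.label = None
        left = parent.add_child(TreeNode(parent.label, 0.0))
        left.label = f"t{label}"
        label += 1
        right = parent.add_child(TreeNode(f"t{label}", 0.0))
        label += 1
        # the split lineage keeps no name; its children start at zero length
        active.extend([left, right])
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length += dt
    # relabel tips deterministically in postorder for stable output
    tree = Tree(root)
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"t{i}"
    return Tree(root)


# ---------------------------------------------------------------------------
# Codon alignments


def _simulate_states(tree: Tree, pi: np.ndarray, P_for, rng,
                     n_sites: int) -> dict[str, np.ndarray]:
    """Evolve i.i.d. sites down the tree by transition-probability sampling.

    ``P_for(node)`` returns the (k, k) transition matrix of the branch
    above ``node``.
    """
    k = len(pi)
    states = {id(tree.root): rng.choice(k, size=n_sites, p=pi)}
    out = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        P = P_for(node)
        parent_states = states[id(node.parent)]
        u = rng.random(n_sites)
        cdf = np.cumsum(P, axis=1)
        child = (u[:, None] > cdf[parent_states]).sum(axis=1)
        states[id(node)] = child
        if node.is_tip:
            out[node.label] = child
    return out


def simulate_codon_alignment(tree: Tree, config: SimulationConfig,
                             seed: int | None = None):
    """Simulate a codon alignment under the configured model.

    Returns ``(alignment, info)`` where ``info`` records the per-site class
    assignment (site models) and the class omegas/weights actually used.
    Codon frequencies are uniform over the 61 sense codons; generators are
    scaled exactly as the fitters scale them, so input branch lengths carry
    the same substitutions-per-site meaning in both directions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pi = np.full(N_CODONS, 1.0 / N_CODONS)
    # borrow the fitters' generator construction for an exact match
    proxy = _CodonLikelihood.__new__(_CodonLikelihood)
    proxy.pi = pi
    from .codon_selection import _structural_masks

    ts, tv, syn, single = _structural_masks()
    pi_col = pi[None, :]
    proxy.A_ts_syn = (ts & syn) * pi_col
    proxy.A_tv_syn = (tv & syn) * pi_col
    proxy.A_ts_non = (ts & ~syn) * pi_col
    proxy.A_tv_non = (tv & ~syn) * pi_col

    n_sites = config.n_codon_sites
    info: dict = {"pi": pi}

    if config.site_model in ("M7", "M8"):
        omegas, weights = discretize_beta(config.beta_p, config.beta_q, config.K)
        if config.site_model == "M8":
            omegas = np.append(omegas, config.omega_s)
            weights = np.append(weights * (1 - config.p1), config.p1)
        Qs = proxy.class_generators(config.kappa, omegas, weights)
        spectra = [_SpectralQ(Q, pi) for Q in Qs]
        site_class = rng.choice(len(omegas), size=n_sites, p=weights)
        info.update(site_class=site_class, omegas=omegas, weights=weights)
        cols = {}
        for c in range(len(omegas)):
            sel = np.where(site_class == c)[0]
            if not len(sel):
                continue
            P_cache = {}

            def P_for(node, _s=spectra[c]):
                t = node.length
                if t not in P_cache:
                    P = _s.P(t)
                    P_cache[t] = P / P.sum(axis=1, keepdims=True)
                return P_cache[t]

            tips = _simulate_states(tree, pi, P_for, rng, len(sel))
            for label, vals in tips.items():
                cols.setdefault(label, np.empty(n_sites, dtype=np.int16))[sel] = vals
        mat = np.stack([cols[t] for t in tree.tip_labels])
        aln = CodonAlignment(tree.tip_labels, mat)
        return aln, info

    if config.site_model in ("one_ratio", "branch_map"):
        ids = tree.branch_ids()
        if config.site_model == "one_ratio":
            omega_map = {ids[id(b)]: config.omega for b in tree.branches()}
        else:
            omega_map = dict(config.branch_omegas)
            missing = {ids[id(b)] for b in tree.branches()} - set(omega_map)
            if missing:
                raise ValidationError(f"branch omegas missing for: {sorted(missing)}")
        cache = {}

        def spectral(w):
            if w not in cache:
                off = proxy.off_diagonal(config.kappa, w)
                mu = proxy.rate_of(off)
                Q = off / mu
                np.fill_diagonal(Q, 0.0)
                np.fill_diagonal(Q, -Q.sum(axis=1))
                cache[w] = _SpectralQ(Q, pi)
            return cache[w]

        def P_for(node):
            P = spectral(omega_map[ids[id(node)]]).P(node.length)
            return P / P.sum(axis=1, keepdims=True)

        tips = _simulate_states(tree, pi, P_for, rng, n_sites)
        mat = np.stack([tips[t] for t in tree.tip_labels])
        info.update(omega_map=omega_map)
        return CodonAlignment(tree.tip_labels, mat), info

    raise ValidationError(f"unknown simulation model {config.site_model!r}")


# ---------------------------------------------------------------------------
# Traits


def simulate_discrete_trait(tree: Tree, model: MkModel, root_state: str,
                            seed: int = 0) -> dict[str, str]:
    """Evolve a discrete character down the tree under the Mk model."""
    if root_state not in model.states:
        raise ValidationError(f"root state {root_state!r} not in model states")
    rng = np.random.default_rng(seed)
    from scipy.linalg import expm

    Q = model.generator()
    k = len(model.states)
    states = {id(tree.root): model.states.index(root_state)}
    out = {}
    cache = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length
        if t not in cache:
            P = np.clip(expm(Q * t), 0.0, None)
            cache[t] = P / P.sum(axis=1, keepdims=True)
        P = cache[t]
        s = rng.choice(k, p=P[states[id(node.parent)]])
        states[id(node)] = s
        if node.is_tip:
            out[node.label] = model.states[s]
    return out


def simulate_continuous_trait(tree: Tree, sigma2: float, root_value: float,
                              seed: int = 0) -> dict[str, float]:
    """Evolve a continuous character by Brownian motion: independent normal
    increments with variance sigma2 * branch length."""
    if sigma2 < 0:
        raise ValidationError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values = {id(tree.root): float(root_value)}
    out = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        step = rng.normal(0.0, np.sqrt(sigma2 * node.length)) if sigma2 > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip:
            out[node.label] = values[id(node)]
    return out


# ---------------------------------------------------------------------------
# Static fixtures transcribed from printed results


OPSIN_GENES = (
    "RH1", "RH2", "OPN1sw1", "OPN1sw2", "OPN1lw",
    "OPN3", "TMT", "TMT2",
    "PARA", "PARIE", "PIN", "VA",
    "OPN5", "RGR", "RRH",
    "OPN4x", "OPN4m",
)

MAMMALIAN_OPSINS = (
    "RH1", "OPN1sw1", "OPN1sw2", "OPN1lw", "OPN3",
    "TMT", "OPN5", "RGR", "RRH", "OPN4m",
)

#: printed tetrapod repertoire sizes
REPERTOIRE_COUNTS = {"amphibians": 16, "reptiles": 17, "birds": 15, "mammals": 10}


@dataclass
class PublishedFixtures:
    opsin_presence: pd.DataFrame
    repertoire_counts: pd.Series
    phenotype_examples: pd.DataFrame


def published_fixtures() -> PublishedFixtures:
    """Static fixtures transcribed from printed text.

    ``opsin_presence`` covers the lineages whose full gene lists are
    printed (mammals; reptiles with the complete set; birds lacking the
    two pineal opsins PARA and PARIE). The identity of the single opsin
    absent in amphibians is figure-only content and is therefore carried
    only in ``repertoire_counts``. ``phenotype_examples`` holds the printed
    human and brown-rat orbit convergence / visual acuity values.
    """
    rows = {}
    rows["mammals"] = [1 if g in MAMMALIAN_OPSINS else 0 for g in OPSIN_GENES]
    rows["reptiles"] = [1] * len(OPSIN_GENES)
    rows["birds"] = [0 if g in ("PARA", "PARIE") else 1 for g in OPSIN_GENES]
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=list(OPSIN_GENES))
    counts = pd.Series(REPERTOIRE_COUNTS, name="n_opsins")
    phenotypes = pd.DataFrame(
        {
            "species_id": ["Homo_sapiens", "Rattus_norvegicus"],
            "activity_pattern": ["diurnal", "nocturnal"],
            "orbit_convergence": [79.3, 32.0],
            "visual_acuity": [64.0, 1.6],
        }
    ).set_index("species_id")
    return PublishedFixtures(presence, counts, phenotypes)
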