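"""Ancestral reconstruction of photic characters on omega-trees.

Discrete characters (activity pattern, VS/UVS vision) evolve under Mk-type
continuous-time Markov chains with equal (ER), symmetric (SYM) or
all-rates-different (ARD) rate matrices; schemes are compared by LRT and
marginal ancestral state probabilities are computed by a two-pass
(inside/outside) conditioning with a flat root prior.

Continuous characters (orbit convergence, visual acuity) are reconstructed
under Brownian motion by generalized least squares, after gating each gene
tree on phylogenetic signal with Moran's I (weights default to inverse
patristic distance on the gene's omega-tree). Estimates surviving the gate
are aggregated across genes as unweighted means with population standard
deviations.

Branch values of the omega-trees serve directly as evolutionary distances,
a modeling choice inherited from the study design rather than endorsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import mannwhitneyu, norm

from ._pruning import mixture_site_loglik
from .codon_selection import lrt
from .omega_tree import OmegaTree
from .phylo_core import MISSING, Tree, ValidationError, patristic_distances

__all__ = [
    "MkModel", "MkFit", "ReconstructionResult", "MoranResult",
    "fit_mk", "marginal_ancestral_states", "compare_mk_schemes",
    "bm_ancestral", "morans_i", "moran_weights", "aggregate_across_genes",
    "wilcoxon_ranksum",
]

_SCHEMES = ("ER", "SYM", "ARD")


def _as_tree(t) -> Tree:
    return t.tree if isinstance(t, OmegaTree) else t


@dataclass
class MkModel:
    """Mk model: k >= 2 states, rate scheme ER / SYM / ARD.

    ``rates`` holds the free rate parameters in deterministic order:
    one value for ER; one per unordered state pair (i < j, lexicographic)
    for SYM; one per ordered pair ((i, j), i != j, lexicographic) for ARD.
    """

    states: list[str]
    scheme: str
    rates: np.ndarray

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValidationError("Mk model needs at least two states")
        if self.scheme not in _SCHEMES:
            raise ValidationError(f"unknown Mk scheme {self.scheme!r}")
        self.rates = np.asarray(self.rates, dtype=float)
        if (self.rates < 0).any():
            raise ValidationError("Mk rates must be non-negative")
        if len(self.rates) != self.n_rates(len(self.states), self.scheme):
            raise ValidationError("rate vector length does not match scheme")

    @staticmethod
    def n_rates(k: int, scheme: str) -> int:
        return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[scheme]

    def generator(self) -> np.ndarray:
        k = len(self.states)
        Q = np.zeros((k, k))
        if self.scheme == "ER":
            Q[:] = self.rates[0]
        elif self.scheme == "SYM":
            idx = 0
            for i in range(k):
                for j in range(i + 1, k):
                    Q[i, j] = Q[j, i] = self.rates[idx]
                    idx += 1
        else:
            idx = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = self.rates[idx]
                        idx += 1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


@dataclass
class MkFit:
    model: MkModel
    lnL: float
    np: int
    converged: bool
    tree: Tree = field(repr=False)
    tip_states: dict = field(repr=False)


@dataclass
class ReconstructionResult:
    """Per-internal-node reconstruction.

    ``table`` holds state probability vectors (discrete; rows sum to 1) or
    estimate/sd columns (continuous). Node ids are internal labels when
    present, else deterministic ``node<i>`` postorder indices; the root is
    labelled ``root`` in addition when unlabelled.
    """

    kind: str
    table: pd.DataFrame
    model: object
    lnL: float | None = None
    extras: dict = field(default_factory=dict)


def _node_ids(tree: Tree):
    ids = {}
    i = 0
    for node in tree.postorder():
        if node.is_tip:
            ids[id(node)] = node.label
        else:
            if node.label:
                ids[id(node)] = node.label
            elif node.parent is None:
                ids[id(node)] = "root"
            else:
                ids[id(node)] = f"node{i}"
            i += 1
    return ids


def _state_codes(tip_states: dict, states: list[str]):
    codes = {}
    index = {s: i for i, s in enumerate(states)}
    for tip, s in tip_states.items():
        if s is None or (isinstance(s, float) and np.isnan(s)):
            codes[tip] = np.array([MISSING])
        else:
            if s not in index:
                raise ValidationError(f"state {s!r} not in model states {states}")
            codes[tip] = np.array([index[s]])
    return codes


def _branch_P_factory(tree: Tree, Q: np.ndarray):
    """exp(Q t) per branch via one eigendecomposition (general, possibly
    non-symmetric); falls back to expm for defective matrices."""
    k = Q.shape[0]
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    use_eig = np.isfinite(cond) and cond < 1e8

    cache = {}

    def P_of(node):
        t = node.length
        if t not in cache:
            if use_eig:
                P = (V * np.exp(lam * t)) @ Vinv
                P = np.real(P)
            else:
                P = linalg.expm(Q * t)
            P = np.clip(P, 0.0, None)
            s = P.sum(axis=1, keepdims=True)
            P = P / np.where(s > 0, s, 1.0)
            cache[t] = P[None]
        return cache[t]

    return P_of


def mk_loglik(tree, tip_states, model: MkModel) -> float:
    """Pruning log-likelihood of a single discrete character under ``model``
    with a flat root prior."""
    tree = _as_tree(tree)
    k = len(model.states)
    codes = _state_codes(tip_states, model.states)
    P_of = _branch_P_factory(tree, model.generator())
    site_ll, _ = mixture_site_loglik(tree, codes, P_of,
                                     np.full(k, 1.0 / k), np.array([1.0]))
    return float(site_ll[0])


def fit_mk(tree, tip_states: dict, scheme: str = "ER", seed: int = 0,
           n_restarts: int = 3, maxiter: int = 500,
           states: list[str] | None = None) -> MkFit:
    """Maximum-likelihood Mk fit on the (omega-)tree.

    Unknown tip states (None/NaN) contribute a partial likelihood of one.
    States default to the sorted set of observed states, in which case
    fewer than two observed states is an error; passing ``states``
    explicitly permits degenerate data (the rate then collapses to its
    lower bound and ancestral reconstruction pins the observed state).
    """
    tree = _as_tree(tree)
    observed = sorted(
        {s for s in tip_states.values()
         if s is not None and not (isinstance(s, float) and np.isnan(s))}
    )
    if states is None:
        if len(observed) < 2:
            raise ValidationError("need at least two observed states to fit an Mk model")
        states = observed
    elif not set(observed) <= set(states):
        raise ValidationError("observed states outside the supplied state space")
    n_rates = MkModel.n_rates(len(states), scheme)

    depth = _as_tree(tree).depths()
    total = max(depth.values())
    rate0 = 1.0 / total if total > 0 else 1.0

    codes = _state_codes(tip_states, states)
    prior = np.full(len(states), 1.0 / len(states))

    def objective(logx):
        model = MkModel(states, scheme, np.exp(logx))
        P_of = _branch_P_factory(tree, model.generator())
        try:
            site_ll, _ = mixture_site_loglik(tree, codes, P_of, prior,
                                             np.array([1.0]))
        except FloatingPointError:
            return 1e10
        val = float(site_ll[0])
        return 1e10 if not np.isfinite(val) else -val

    rng = np.random.default_rng(seed)
    bounds = [(-15.0, 8.0)] * n_rates
    best, best_f, converged = None, np.inf, False
    for r in range(n_restarts):
        x0 = np.full(n_rates, np.log(rate0))
        if r:
            x0 = x0 + rng.normal(0.0, 1.0, n_rates)
        x0 = np.clip(x0, -15.0, 8.0)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-12})
        if res.fun < best_f:
            best, best_f = res.x, float(res.fun)
        converged = converged or bool(res.success)
    model = MkModel(states, scheme, np.exp(best))
    return MkFit(model=model, lnL=-best_f, np=n_rates, converged=converged,
                 tree=tree, tip_states=dict(tip_states))


def marginal_ancestral_states(tree, tip_states: dict,
                              model: MkModel | MkFit) -> ReconstructionResult:
    """Marginal state probabilities at every internal node.

    Two-pass conditioning: inside (pruning) partials from the tips, outside
    partials from a flat root prior; the marginal at a node is the
    normalized product of the two.
    """
    if isinstance(model, MkFit):
        model = model.model
    tree = _as_tree(tree)
    states = model.states
    k = len(states)
    codes = _state_codes(tip_states, states)
    tree.check_tip_coverage(codes)
    P_of = _branch_P_factory(tree, model.generator())
    prior = np.full(k, 1.0 / k)

    inside = {}
    for node in tree.postorder():
        if node.is_tip:
            c = codes[node.label][0]
            vec = np.ones(k) if c == MISSING else np.eye(k)[c]
        else:
            vec = np.ones(k)
            for child in node.children:
                P = P_of(child)[0]
                vec = vec * (P @ inside[id(child)])
        m = vec.max()
        inside[id(node)] = vec / m if m > 0 else vec

    outside = {id(tree.root): prior.copy()}
    for node in tree.preorder():
        for child in node.children:
            if child.is_tip:
                continue
            acc = outside[id(node)].copy()
            for sib in node.children:
                if sib is child:
                    continue
                acc = acc * (P_of(sib)[0] @ inside[id(sib)])
            P = P_of(child)[0]
            vec = acc @ P
            m = vec.max()
            outside[id(child)] = vec / m if m > 0 else vec

    ids = _node_ids(tree)
    rows, labels = [], []
    lnL_root = None
    for node in tree.postorder():
        if node.is_tip:
            continue
        joint = inside[id(node)] * outside[id(node)]
        total = joint.sum()
        if total <= 0:
            raise ValidationError("zero marginal likelihood at an internal node")
        rows.append(joint / total)
        labels.append(ids[id(node)])
    table = pd.DataFrame(rows, index=labels, columns=states)
    lnL_root = mk_loglik(tree, tip_states, model)
    return ReconstructionResult(kind="discrete", table=table, model=model,
                                lnL=lnL_root)


def compare_mk_schemes(fit_null: MkFit, fit_alt: MkFit,
                       df_override: int | None = None):
    """LRT between two nested Mk fits (e.g. SYM vs ARD).

    df defaults to the free-parameter difference; the override exists
    because published analyses sometimes report df = 1 for this comparison.
    Returns (statistic, p_value, df).
    """
    df = df_override if df_override is not None else max(1, fit_alt.np - fit_null.np)
    stat, p = lrt(fit_null.lnL, fit_alt.lnL, df=df)
    return stat, p, df


# ---------------------------------------------------------------------------
# Brownian motion


def _mrca_depth_matrix(tree: Tree, tips):
    depth = tree.depths()
    chains = []
    for tip in tips:
        chain = {}
        node = tip
        while node is not None:
            chain[id(node)] = depth[id(node)]
            node = node.parent
        chains.append(chain)
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depth[id(tips[i])]
        for j in range(i + 1, n):
            node = tips[j]
            while id(node) not in chains[i]:
                node = node.parent
            C[i, j] = C[j, i] = depth[id(node)]
    return C, depth, chains


def bm_ancestral(tree, tip_values: dict) -> ReconstructionResult:
    """ML ancestral estimates under Brownian motion (GLS form).

    Tips without values are ignored; at least two valued tips are required.
    sigma^2 is the ML estimate; per-node SDs account for the uncertainty of
    the root (GLS mean) as well as the node's conditional variance.
    """
    tree = _as_tree(tree)
    valued = {k: float(v) for k, v in tip_values.items()
              if v is not None and np.isfinite(v)}
    if len(valued) < 2:
        raise ValidationError("need at least two tips with values")
    tree.check_tip_coverage(valued)
    tips = [t for t in tree.tips() if t.label in valued]
    y = np.array([valued[t.label] for t in tips])

    C, depth, chains = _mrca_depth_matrix(tree, tips)
    if np.max(np.diag(C)) <= 0:
        raise ValidationError("zero total tree depth; BM distances undefined")
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular BM covariance (duplicate zero-length tips?)"
        ) from exc
    one = np.ones(len(tips))
    denom = one @ Cinv @ one
    mu = float(one @ Cinv @ y / denom)
    resid = y - mu
    n = len(tips)
    sigma2 = float(resid @ Cinv @ resid / n)

    ids = _node_ids(tree)
    rows, labels = [], []
    for node in tree.postorder():
        if node.is_tip:
            continue
        # cov between node and each valued tip = depth of their MRCA
        anc = set()
        cursor = node
        while cursor is not None:
            anc.add(id(cursor))
            cursor = cursor.parent
        c = np.empty(n)
        for i, tip in enumerate(tips):
            cursor = tip
            while id(cursor) not in anc:
                cursor = cursor.parent
            c[i] = depth[id(cursor)]
        a = Cinv @ c
        est = mu + float(a @ resid)
        var_scale = depth[id(node)] - float(c @ a) + (1.0 - float(one @ a)) ** 2 / denom
        sd = float(np.sqrt(sigma2 * max(var_scale, 0.0)))
        rows.append((est, sd))
        labels.append(ids[id(node)])
    table = pd.DataFrame(rows, index=labels, columns=["estimate", "sd"])
    return ReconstructionResult(kind="continuous", table=table,
                                model={"sigma2": sigma2, "root": mu},
                                extras={"n_tips": n})


# ---------------------------------------------------------------------------
# Moran's I


class MoranResult(NamedTuple):
    I: float
    expected: float
    variance: float
    p_value: float


def moran_weights(otree, tips=None) -> pd.DataFrame:
    """Inverse-patristic-distance weights on the (omega-)tree, zero
    diagonal, no row normalization."""
    tree = _as_tree(otree)
    d = patristic_distances(tree)
    if tips is not None:
        d = d.loc[list(tips), list(tips)]
    vals = d.to_numpy(dtype=float)
    off = ~np.eye(len(vals), dtype=bool)
    if (vals[off] <= 0).any():
        raise ValidationError("zero patristic distance between distinct tips; "
                              "inverse-distance weights undefined")
    w = np.zeros_like(vals)
    w[off] = 1.0 / vals[off]
    return pd.DataFrame(w, index=d.index, columns=d.columns)


def morans_i(values, weights) -> MoranResult:
    """Moran's I with E[I] = -1/(n-1) and a normal-approximation two-sided
    p-value (variance under the normality assumption)."""
    if isinstance(weights, pd.DataFrame):
        if isinstance(values, pd.Series):
            values = values.loc[weights.index]
        weights = weights.to_numpy(dtype=float)
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("Moran's I needs at least three observations")
    if W.shape != (n, n):
        raise ValidationError("weight matrix shape does not match values")
    if np.diag(W).any():
        raise ValidationError("weight matrix must have a zero diagonal")
    if not np.isfinite(W).all():
        raise ValidationError("non-finite weights")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValidationError("constant values; Moran's I undefined")
    S0 = W.sum()
    I = n / S0 * float(z @ W @ z) / ss
    expected = -1.0 / (n - 1)
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    variance = (n * n * S1 - n * S2 + 3.0 * S0 * S0) / ((n * n - 1.0) * S0 * S0) \
        - expected ** 2
    sd = np.sqrt(variance)
    p = 2.0 * norm.sf(abs(I - expected) / sd) if sd > 0 else 1.0
    return MoranResult(float(I), float(expected), float(variance), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# Cross-gene aggregation and the activity/orbit test


def aggregate_across_genes(gene_results: dict, moran_pvalues: dict | None = None,
                           threshold: float | None = None,
                           clade_counts: dict | None = None,
                           min_species: int = 2) -> pd.DataFrame:
    """Unweighted per-node mean and population SD across surviving genes.

    ``gene_results`` maps gene -> {node: estimate}. Genes failing the
    Moran's I gate (p >= threshold) contribute nothing; per gene, nodes
    whose clade is represented by fewer than ``min_species`` sampled
    species (``clade_counts[gene][node]``) are excluded.
    """
    surviving = []
    for gene in gene_results:
        if moran_pvalues is not None and threshold is not None:
            if not (moran_pvalues[gene] < threshold):
                continue
        surviving.append(gene)
    nodes: list = []
    for gene in surviving:
        for node in gene_results[gene]:
            if node not in nodes:
                nodes.append(node)
    rows = []
    for node in nodes:
        vals = []
        for gene in surviving:
            if node not in gene_results[gene]:
                continue
            if clade_counts is not None:
                n_rep = clade_counts.get(gene, {}).get(node)
                if n_rep is not None and n_rep < min_species:
                    continue
            vals.append(gene_results[gene][node])
        if vals:
            arr = np.asarray(vals, dtype=float)
            rows.append((node, arr.mean(), arr.std(ddof=0), len(arr)))
        else:
            rows.append((node, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["node", "mean", "sd", "n_genes"]).set_index("node")


def wilcoxon_ranksum(group_a, group_b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie
    correction. Returns (U statistic for group_a, two-sided p).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
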