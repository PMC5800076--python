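"""Codon substitution models and site-/branch-level selection tests.

The model is a Goldman–Yang-style 61-state codon process: an off-diagonal
rate is zero for multi-nucleotide changes and otherwise proportional to the
target codon frequency, multiplied by the transition/transversion ratio
kappa for transitions and by omega = dN/dS for nonsynonymous changes.

Site models follow the classic beta family:

* M7   — omega ~ Beta(p, q) on (0, 1), discretized into K equal-probability
         categories represented by their bin means;
* M8   — M7 plus an extra category with weight p1 and omega_s >= 1
         (bounded below at 1 so that M8a is nested on the boundary);
* M8a  — M8 with omega_s fixed at 1 (a neutral class).

Branch models assign one omega to every branch (one-ratio), a separate
omega to a designated foreground set (two-ratio), or one omega per branch
(free-ratios, which yields the omega-tree used downstream).

Generators are scaled to one expected substitution per unit time — at the
model's omega mixture for site models, per branch for branch models — so
input branch lengths keep their substitutions-per-site meaning. Positively
selected sites are identified by naive empirical Bayes at the maximum
likelihood estimates, flagged at posterior > 0.75.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import linalg, optimize
from scipy.special import betainc
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from ._pruning import mixture_site_loglik
from .phylo_core import (
    CODON_AMINO_ACIDS,
    CODONS,
    MISSING,
    CodonAlignment,
    PhyloError,
    Tree,
    ValidationError,
)

logger = logging.getLogger(__name__)

N_CODONS = 61
POSTERIOR_FLAG_THRESHOLD = 0.75

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@lru_cache(maxsize=1)
def _structural_masks():
    """Boolean (61, 61) masks for single-nucleotide codon changes."""
    ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    tv = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    syn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            if diff[0] in _TRANSITIONS:
                ts[i, j] = True
            else:
                tv[i, j] = True
            if CODON_AMINO_ACIDS[i] == CODON_AMINO_ACIDS[j]:
                syn[i, j] = True
    single = ts | tv
    return ts, tv, syn, single


@dataclass
class CodonModelParams:
    """Parameter bundle for the codon models.

    Site-model fields (``beta_p``, ``beta_q``, ``p1``, ``omega_s``) and the
    single-``omega`` field are used as context demands.
    """

    kappa: float
    codon_freqs: np.ndarray
    omega: float | None = None
    beta_p: float | None = None
    beta_q: float | None = None
    p1: float | None = None
    omega_s: float | None = None

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        _check_freqs(self.codon_freqs)
        for name in ("beta_p", "beta_q"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.p1 is not None and not (0.0 <= self.p1 <= 1.0):
            raise ValidationError("p1 must lie in [0, 1]")
        if self.omega is not None and self.omega < 0:
            raise ValidationError("omega must be non-negative")


def _check_freqs(pi):
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValidationError(f"codon frequency vector must have length {N_CODONS}")
    if (pi <= 0).any():
        raise ValidationError("codon frequencies must be positive")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValidationError("codon frequencies must sum to 1")
    return pi / pi.sum()


@dataclass
class BranchEstimate:
    branch_id: str
    omega: float
    dN: float
    dS: float
    length: float  # branch length actually used (input length x rate multiplier)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood codon-model fit."""

    model_name: str
    estimates: dict
    lnL: float
    np: int
    converged: bool = True
    per_branch: list[BranchEstimate] | None = None
    site_class_omegas: np.ndarray | None = None
    site_class_weights: np.ndarray | None = None
    per_site_class_loglik: np.ndarray | None = field(default=None, repr=False)
    per_site_class_posteriors: np.ndarray | None = field(default=None, repr=False)
    message: str = ""


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities


def build_codon_rate_matrix(params: CodonModelParams, omega: float,
                            scale: bool = True) -> np.ndarray:
    """GY94-style generator for a single omega.

    Off-diagonal ``q_ij`` is zero for multi-nucleotide changes and otherwise
    ``pi_j * kappa^[transition] * omega^[nonsynonymous]``; rows sum to zero.
    With ``scale=True`` the matrix is normalized to one expected substitution
    per unit time at its own omega (mixtures are jointly rescaled by the
    fitting code instead).
    """
    if omega < 0:
        raise ValidationError("omega must be non-negative")
    pi = _check_freqs(params.codon_freqs)
    ts, tv, syn, single = _structural_masks()
    rate = np.where(ts, params.kappa, 1.0) * single
    factor = np.where(syn, 1.0, omega)
    Q = rate * factor * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -np.dot(pi, np.diag(Q))
        if mu <= 0:
            raise ValidationError("degenerate rate matrix (zero total rate)")
        Q = Q / mu
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix exp(Q t); tiny negative entries are clipped."""
    if t < 0:
        raise ValidationError("time must be non-negative")
    P = linalg.expm(np.asarray(Q, dtype=float) * t)
    if P.min() < -1e-12:
        logger.warning("transition matrix entry %g clipped to 0", P.min())
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


class _SpectralQ:
    """Eigendecomposition of a reversible generator for cheap exp(Qt)."""

    def __init__(self, Q, pi):
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        self.lam = lam
        self.left = U / sq[:, None]
        self.right = (U * sq[:, None]).T

    def P(self, t):
        out = (self.left * np.exp(self.lam * t)) @ self.right
        return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Beta discretization


def discretize_beta(p: float, q: float, K: int):
    """K equal-probability categories of Beta(p, q), each represented by its
    bin mean. Returns (omegas, weights) with all weights 1/K.

    Bin means are exact: the mean of Beta(p, q) truncated to a quantile bin
    is ``mean * (I_b(p+1, q) - I_a(p+1, q)) * K`` with I the regularized
    incomplete beta function.
    """
    if p <= 0 or q <= 0:
        raise ValidationError("beta shapes must be positive")
    if K < 1:
        raise ValidationError("K must be >= 1")
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    mean = p / (p + q)
    upper = betainc(p + 1.0, q, edges[1:])
    lower = betainc(p + 1.0, q, edges[:-1])
    omegas = mean * (upper - lower) * K
    weights = np.full(K, 1.0 / K)
    return omegas, weights


# ---------------------------------------------------------------------------
# Codon frequency estimators


def empirical_codon_freqs(alignment: CodonAlignment, method: str = "F3x4",
                          pseudocount: float = 0.5) -> np.ndarray:
    """Codon frequencies from the alignment: F3x4 (position-specific
    nucleotide products, codeml's default style) or F61 (observed codons).
    A small pseudocount keeps every sense codon attainable."""
    codes = alignment.codons
    observed = codes[codes != MISSING]
    if method == "F61":
        counts = np.bincount(observed, minlength=N_CODONS).astype(float)
        counts += pseudocount
        return counts / counts.sum()
    if method != "F3x4":
        raise ValidationError(f"unknown frequency model {method!r}")
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    pos_counts = np.full((3, 4), pseudocount)
    for c in observed:
        codon = CODONS[c]
        for pos in range(3):
            pos_counts[pos, nt_index[codon[pos]]] += 1
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, nt_index[c[0]]]
            * pos_freqs[1, nt_index[c[1]]]
            * pos_freqs[2, nt_index[c[2]]]
            for c in CODONS
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Pruning likelihood (public wrapper)


def _tip_codes(alignment: CodonAlignment):
    return {sid: alignment.codons[i] for i, sid in enumerate(alignment.sequence_ids)}


def pruning_loglik(tree: Tree, alignment: CodonAlignment, Q,
                   root_freqs: np.ndarray,
                   class_weights=None) -> np.ndarray:
    """Per-site log-likelihoods by Felsenstein pruning.

    ``Q`` may be a single (61, 61) generator, a (C, 61, 61) stack of
    per-site-class generators (mixed with ``class_weights``), or a dict
    mapping branch ids (see :meth:`Tree.branch_ids`) to either.  MISSING
    codons contribute a partial likelihood of one.
    """
    pi = np.asarray(root_freqs, dtype=float)
    if class_weights is None:
        class_weights = np.array([1.0])

    def as_stack(q):
        q = np.asarray(q, dtype=float)
        return q[None] if q.ndim == 2 else q

    ids = tree.branch_ids()
    if isinstance(Q, dict):
        stacks = {bid: as_stack(q) for bid, q in Q.items()}
        missing = {ids[id(n)] for n in tree.branches()} - set(stacks)
        if missing:
            raise ValidationError(f"no generator supplied for branches: {sorted(missing)}")

        def P_of(node):
            stack = stacks[ids[id(node)]]
            return np.stack([transition_probabilities(q, node.length) for q in stack])
    else:
        stack = as_stack(Q)

        def P_of(node):
            return np.stack([transition_probabilities(q, node.length) for q in stack])

    site_ll, _ = mixture_site_loglik(tree, _tip_codes(alignment), P_of, pi,
                                     np.asarray(class_weights, dtype=float))
    return site_ll


# ---------------------------------------------------------------------------
# Likelihood engine used by the fitters


class _CodonLikelihood:
    """Caches alignment/tree structure for repeated likelihood evaluations."""

    def __init__(self, alignment: CodonAlignment, tree: Tree,
                 freq_model: str = "F3x4"):
        tree.check_tip_coverage(alignment.sequence_ids)
        extra = set(tree.tip_labels) - set(alignment.sequence_ids)
        if extra:
            raise ValidationError(
                f"tree tips without alignment rows: {sorted(extra)}"
            )
        self.tree = tree
        self.alignment = alignment
        self.tips = _tip_codes(alignment)
        self.pi = empirical_codon_freqs(alignment, freq_model)
        ts, tv, syn, single = _structural_masks()
        pi_col = self.pi[None, :]
        self.A_ts_syn = (ts & syn) * pi_col
        self.A_tv_syn = (tv & syn) * pi_col
        self.A_ts_non = (ts & ~syn) * pi_col
        self.A_tv_non = (tv & ~syn) * pi_col
        self.branches = tree.branches()
        self.branch_ids = tree.branch_ids()
        self.n_sites = alignment.n_codon_sites

    def off_diagonal(self, kappa, omega):
        return (self.A_tv_syn + kappa * self.A_ts_syn) + omega * (
            self.A_tv_non + kappa * self.A_ts_non
        )

    def rate_of(self, Qoff):
        return float(self.pi @ Qoff.sum(axis=1))

    def class_generators(self, kappa, omegas, weights):
        """Jointly scaled generators: one expected substitution per unit
        time under the omega mixture."""
        offs = [self.off_diagonal(kappa, w) for w in omegas]
        rates = np.array([self.rate_of(o) for o in offs])
        total = float(np.dot(weights, rates))
        Qs = []
        for off in offs:
            Q = off / total
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            Qs.append(Q)
        return Qs

    def site_class_loglik(self, kappa, omegas, weights, rate_mult=1.0):
        """(site_loglik, class_loglik) under shared branch lengths."""
        Qs = self.class_generators(kappa, omegas, weights)
        spectra = [_SpectralQ(Q, self.pi) for Q in Qs]

        def P_of(node):
            t = node.length * rate_mult
            return np.stack([s.P(t) for s in spectra])

        return mixture_site_loglik(self.tree, self.tips, P_of, self.pi,
                                   np.asarray(weights, dtype=float))

    def branch_model_loglik(self, kappa, omega_of_branch, rate_mult=1.0):
        """Log-likelihood with one omega per branch, each generator scaled
        to unit rate on its own branch."""
        cache: dict[float, _SpectralQ] = {}

        def spectral(omega):
            if omega not in cache:
                off = self.off_diagonal(kappa, omega)
                mu = self.rate_of(off)
                Q = off / mu
                np.fill_diagonal(Q, 0.0)
                np.fill_diagonal(Q, -Q.sum(axis=1))
                cache[omega] = _SpectralQ(Q, self.pi)
            return cache[omega]

        def P_of(node):
            s = spectral(omega_of_branch[self.branch_ids[id(node)]])
            return s.P(node.length * rate_mult)[None]

        site_ll, _ = mixture_site_loglik(self.tree, self.tips, P_of, self.pi,
                                         np.array([1.0]))
        return float(site_ll.sum())

    def syn_fractions(self, kappa, omega):
        """(rho_S, rho_N): fractions of the substitution flux that are
        synonymous/nonsynonymous under a unit-rate generator."""
        _, _, syn, _ = _structural_masks()
        off = self.off_diagonal(kappa, omega)
        mu = self.rate_of(off)
        flux = self.pi[:, None] * off / mu
        rho_s = float(flux[syn].sum())
        return rho_s, 1.0 - rho_s


def _multistart(objective, x0, bounds, seed, n_restarts, maxiter):
    """Bounded quasi-Newton with seeded restarts; returns (x, f, converged)."""
    rng = np.random.default_rng(seed)
    best_x, best_f, converged = None, np.inf, False
    starts = [np.asarray(x0, dtype=float)]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(max(0, n_restarts - 1)):
        jitter = np.asarray(x0) * np.exp(rng.normal(0.0, 0.35, size=len(x0)))
        starts.append(np.clip(jitter, lo, hi))
    for start in starts:
        res = optimize.minimize(
            objective, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
            converged = converged or bool(res.success)
        elif res.success:
            converged = True
    if not converged:
        logger.warning("optimizer did not report convergence after %d starts",
                       len(starts))
    return best_x, best_f, converged


# ---------------------------------------------------------------------------
# Site-model fitting


def _site_model_classes(model, p, q, K, p1, omega_s):
    omegas, weights = discretize_beta(p, q, K)
    if model == "M7":
        return omegas, weights
    omegas = np.append(omegas, omega_s)
    weights = np.append(weights * (1.0 - p1), p1)
    return omegas, weights


def fit_site_model(alignment: CodonAlignment, tree: Tree, model: str = "M7",
                   K: int = 10, seed: int = 0, freq_model: str = "F3x4",
                   n_restarts: int = 3, fix_p1: float | None = None,
                   optimize_rate: bool = True, maxiter: int = 500) -> FitResult:
    """Fit M7, M8 or M8a by bounded multi-start maximum likelihood.

    Branch lengths are taken from the input tree; by default a single rate
    multiplier is co-estimated (``optimize_rate=False`` pins it at 1).
    ``fix_p1`` pins the extra-class weight (``fix_p1=0`` collapses M8 onto
    M7, which is useful for nesting checks).
    """
    if model not in ("M7", "M8", "M8a"):
        raise ValidationError(f"unknown site model {model!r}")
    engine = _CodonLikelihood(alignment, tree, freq_model)

    names = ["kappa", "beta_p", "beta_q"]
    x0 = [2.0, 0.8, 1.2]
    bounds = [(0.05, 99.0), (0.005, 99.0), (0.005, 99.0)]
    if model in ("M8", "M8a") and fix_p1 is None:
        names.append("p1")
        x0.append(0.1)
        bounds.append((0.0, 1.0))
    if model == "M8":
        names.append("omega_s")
        x0.append(2.0)
        bounds.append((1.0, 99.0))
    if optimize_rate:
        names.append("rate")
        x0.append(1.0)
        bounds.append((0.01, 100.0))

    def unpack(x):
        d = dict(zip(names, x))
        p1 = d.get("p1", fix_p1 if fix_p1 is not None else 0.0)
        omega_s = d.get("omega_s", 1.0)
        return d["kappa"], d["beta_p"], d["beta_q"], p1, omega_s, d.get("rate", 1.0)

    def objective(x):
        kappa, p, q, p1, omega_s, rate = unpack(x)
        try:
            omegas, weights = _site_model_classes(model, p, q, K, p1, omega_s)
            site_ll, _ = engine.site_class_loglik(kappa, omegas, weights, rate)
        except (ValidationError, FloatingPointError):
            return 1e10
        total = site_ll.sum()
        return 1e10 if not np.isfinite(total) else -float(total)

    x, f, converged = _multistart(objective, x0, bounds, seed, n_restarts, maxiter)
    kappa, p, q, p1, omega_s, rate = unpack(x)
    omegas, weights = _site_model_classes(model, p, q, K, p1, omega_s)
    site_ll, class_ll = engine.site_class_loglik(kappa, omegas, weights, rate)

    estimates = {"kappa": kappa, "beta_p": p, "beta_q": q, "rate": rate}
    if model in ("M8", "M8a"):
        estimates["p1"] = p1
    if model == "M8":
        estimates["omega_s"] = omega_s
    return FitResult(
        model_name=model,
        estimates=estimates,
        lnL=float(site_ll.sum()),
        np=len(names),
        converged=converged,
        site_class_omegas=omegas,
        site_class_weights=weights,
        per_site_class_loglik=class_ll,
        message="" if converged else "optimizer did not converge",
    )


def site_posteriors(fit: FitResult, threshold: float = POSTERIOR_FLAG_THRESHOLD):
    """Naive empirical Bayes site-class posteriors at the MLEs.

    Returns ``(posteriors, flagged)``: posteriors is (n_sites, n_classes)
    with rows summing to one; flagged lists 0-based sites whose posterior
    mass on the positively-selected class (omega >= 1, M8 only) exceeds the
    acceptance threshold.
    """
    if fit.per_site_class_loglik is None:
        raise ValidationError("fit carries no per-site class likelihoods")
    if not fit.converged:
        logger.warning("computing posteriors from a non-converged fit")
    logw = np.log(np.maximum(fit.site_class_weights, 1e-300))
    log_post = fit.per_site_class_loglik + logw[:, None]
    log_post -= log_post.max(axis=0, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=0, keepdims=True)
    post = post.T  # (n_sites, n_classes)
    flagged = []
    # only the extra class counts as positive selection, and only when its
    # fitted omega actually exceeds one (at the boundary it is neutral)
    if fit.model_name == "M8" and fit.estimates.get("omega_s", 1.0) > 1.0 + 1e-6:
        flagged = list(np.where(post[:, -1] > threshold)[0])
    fit.per_site_class_posteriors = post
    return post, flagged


# ---------------------------------------------------------------------------
# Branch-model fitting


def fit_branch_model(alignment: CodonAlignment, tree: Tree,
                     scheme: str = "one_ratio", foreground=None,
                     seed: int = 0, freq_model: str = "F3x4",
                     n_restarts: int = 3, optimize_rate: bool = True,
                     fix_foreground_equal_background: bool = False,
                     maxiter: int = 1000) -> FitResult:
    """Fit the one-ratio, two-ratio or free-ratios branch model.

    ``foreground`` (two-ratio only) is a non-empty collection of branch ids
    — tip labels, internal labels, or the deterministic ``N<k>`` ids from
    :meth:`Tree.branch_ids`. Free-ratios returns per-branch (omega, dN, dS)
    estimates, the raw material of the omega-tree.
    """
    if scheme not in ("one_ratio", "two_ratio", "free_ratios"):
        raise ValidationError(f"unknown branch scheme {scheme!r}")
    engine = _CodonLikelihood(alignment, tree, freq_model)
    ids = engine.branch_ids
    all_ids = [ids[id(b)] for b in engine.branches]

    if scheme == "two_ratio":
        if not foreground:
            raise ValidationError("two_ratio requires a non-empty foreground set")
        foreground = set(foreground)
        unknown = foreground - set(all_ids)
        if unknown:
            raise ValidationError(f"foreground branches not in tree: {sorted(unknown)}")

    names = ["kappa"]
    x0 = [2.0]
    bounds = [(0.05, 99.0)]
    if scheme == "one_ratio":
        names += ["omega"]
        x0 += [0.4]
        bounds += [(1e-6, 99.0)]
    elif scheme == "two_ratio":
        names += ["omega_background"]
        x0 += [0.4]
        bounds += [(1e-6, 99.0)]
        if not fix_foreground_equal_background:
            names += ["omega_foreground"]
            x0 += [0.6]
            bounds += [(1e-6, 99.0)]
    else:
        for bid in all_ids:
            names.append(f"omega:{bid}")
            x0.append(0.4)
            bounds.append((1e-6, 99.0))
    if optimize_rate:
        names.append("rate")
        x0.append(1.0)
        bounds.append((0.01, 100.0))

    def omega_map(d):
        if scheme == "one_ratio":
            return {bid: d["omega"] for bid in all_ids}
        if scheme == "two_ratio":
            fg = d.get("omega_foreground", d["omega_background"])
            return {
                bid: (fg if bid in foreground else d["omega_background"])
                for bid in all_ids
            }
        return {bid: d[f"omega:{bid}"] for bid in all_ids}

    def objective(x):
        d = dict(zip(names, x))
        try:
            lnL = engine.branch_model_loglik(d["kappa"], omega_map(d),
                                             d.get("rate", 1.0))
        except (ValidationError, FloatingPointError):
            return 1e10
        return 1e10 if not np.isfinite(lnL) else -lnL

    x, f, converged = _multistart(objective, x0, bounds, seed, n_restarts, maxiter)
    d = dict(zip(names, x))
    rate = d.get("rate", 1.0)
    omegas = omega_map(d)
    lnL = engine.branch_model_loglik(d["kappa"], omegas, rate)

    rho_s1, rho_n1 = engine.syn_fractions(d["kappa"], 1.0)
    per_branch = []
    for node in engine.branches:
        bid = ids[id(node)]
        w = omegas[bid]
        rho_s, rho_n = engine.syn_fractions(d["kappa"], w)
        t = node.length * rate
        per_branch.append(BranchEstimate(
            branch_id=bid,
            omega=float(w),
            dN=float(t * rho_n / rho_n1),
            dS=float(t * rho_s / rho_s1),
            length=float(t),
        ))

    return FitResult(
        model_name=scheme,
        estimates=d,
        lnL=float(lnL),
        np=len(names),
        converged=converged,
        per_branch=per_branch,
        message="" if converged else "optimizer did not converge",
    )


# ---------------------------------------------------------------------------
# Tests and corrections


def lrt(lnL0: float, lnL1: float, df: int = 1, tolerance: float = 1e-6):
    """Likelihood-ratio test: statistic 2(lnL1 - lnL0) clipped at zero,
    upper-tail chi-squared p-value with ``df`` degrees of freedom."""
    if df < 1:
        raise ValidationError("df must be >= 1")
    if lnL1 < lnL0 - tolerance:
        logger.warning(
            "alternative lnL (%.6f) below null (%.6f); statistic clipped at 0",
            lnL1, lnL0,
        )
    stat = max(0.0, 2.0 * (lnL1 - lnL0))
    return stat, float(chi2.sf(stat, df))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    return alpha / n_tests
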