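"""Omega-tree construction, root-to-tip linearization and outlier scanning.

An omega-tree is the species tree with each branch length replaced by that
branch's free-ratios dN/dS estimate. Branches with an implausibly large
ratio (omega > 10, typically driven by near-zero dS) are recalculated once
as dN over the median dS of all branches with positive dS, and flagged.

The omega-lineage of a tip is the sum of omega values along its
root-to-tip path (a tree linearization). Lineages are standardized
robustly — subtract the median, divide by the interquartile range — and
tips beyond a configurable threshold on that scale are reported as
candidates for two-ratio branch tests. The linearization is weak on
internal branches by construction, so only terminal lineages are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_selection import BranchEstimate, FitResult
from .phylo_core import Tree, ValidationError

#: omega above which a branch estimate is considered an artefact of tiny dS
OUTLIER_OMEGA_CUTOFF = 10.0
#: default flag threshold on the median/IQR scale (box-plot convention)
DEFAULT_OUTLIER_THRESHOLD = 1.5


@dataclass
class OmegaTree:
    """Tree whose branch values are omega estimates, with provenance."""

    tree: Tree
    provenance: dict[str, str] = field(default_factory=dict)  # branch id -> direct|recalculated
    estimates: dict[str, BranchEstimate] = field(default_factory=dict)

    def __post_init__(self):
        for node in self.tree.branches():
            if node.length < 0:
                raise ValidationError("omega-tree branch values must be >= 0")


def build_omega_tree(tree: Tree, per_branch, cutoff: float = OUTLIER_OMEGA_CUTOFF) -> OmegaTree:
    """Assemble an omega-tree from per-branch (id, omega, dN, dS) estimates.

    ``per_branch`` is a list of :class:`BranchEstimate` (or (id, omega, dN,
    dS) tuples) or a :class:`FitResult` from the free-ratios model. Every
    branch of ``tree`` must have an estimate. Branches with omega strictly
    above ``cutoff`` are recalculated once as dN / median(dS over branches
    with dS > 0) and flagged ``recalculated``; the recalculation is not
    iterated even if the substitute still exceeds the cutoff.
    """
    if isinstance(per_branch, FitResult):
        per_branch = per_branch.per_branch or []
    ests: dict[str, BranchEstimate] = {}
    for item in per_branch:
        if isinstance(item, BranchEstimate):
            est = item
        else:
            bid, omega, dN, dS = item[:4]
            est = BranchEstimate(bid, float(omega), float(dN), float(dS), np.nan)
        ests[est.branch_id] = est

    out = tree.copy()
    ids = out.branch_ids()
    wanted = {ids[id(n)] for n in out.branches()}
    missing = wanted - set(ests)
    if missing:
        raise ValidationError(f"no omega estimate for branches: {sorted(missing)}")

    positive_ds = [e.dS for e in ests.values() if e.branch_id in wanted and e.dS > 0]
    median_ds = float(np.median(positive_ds)) if positive_ds else None

    provenance = {}
    for node in out.branches():
        bid = ids[id(node)]
        est = ests[bid]
        if est.omega > cutoff:
            if median_ds is None:
                raise ValidationError(
                    "all dS are zero; median-dS recalculation undefined"
                )
            node.length = est.dN / median_ds
            provenance[bid] = "recalculated"
        else:
            node.length = est.omega
            provenance[bid] = "direct"
    return OmegaTree(out, provenance, {b: ests[b] for b in wanted})


def omega_lineages(otree: OmegaTree | Tree) -> pd.Series:
    """Per-tip omega-lineage: the sum of root-to-tip branch omegas."""
    tree = otree.tree if isinstance(otree, OmegaTree) else otree
    depth = tree.depths()
    return pd.Series(
        {t.label: depth[id(t)] for t in tree.tips()}, name="omega_lineage"
    ).sort_index()


def standardize_scores(values) -> pd.Series:
    """Robust standardization: (x - median) / IQR.

    Quartiles use linear interpolation between order statistics (numpy's
    default), so {1..5} maps to {-1, -0.5, 0, 0.5, 1}. Raises if the IQR
    is zero or fewer than two distinct values are supplied.
    """
    s = pd.Series(values, dtype=float)
    if s.nunique() < 2:
        raise ValidationError("need at least two distinct values to standardize")
    q1, med, q3 = np.percentile(s.to_numpy(), [25, 50, 75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValidationError("interquartile range is zero")
    return (s - med) / iqr


def flag_outliers(standardized, threshold: float = DEFAULT_OUTLIER_THRESHOLD):
    """Tips whose |standardized score| exceeds ``threshold``.

    Returns ``(flagged, report)``: the flagged tip set and a ranked report
    of all tips (descending |score|).
    """
    if not threshold > 0:
        raise ValidationError("threshold must be positive")
    s = pd.Series(standardized, dtype=float)
    report = pd.DataFrame({
        "score": s,
        "abs_score": s.abs(),
        "outlier": s.abs() > threshold,
    }).sort_values("abs_score", ascending=False)
    return set(report.index[report["outlier"]]), report


def lineage_scan(otree: OmegaTree | Tree,
                 threshold: float = DEFAULT_OUTLIER_THRESHOLD):
    """Convenience: linearize, standardize, flag. Returns (flagged, report)
    with the raw lineage attached to the report."""
    raw = omega_lineages(otree)
    flagged, report = flag_outliers(standardize_scores(raw), threshold)
    report = report.join(raw.rename("raw_lineage"))
    return flagged, report


def omega_tree_table(otree: OmegaTree) -> pd.DataFrame:
    """Per-branch omega/dN/dS table (supplementary-table shaped)."""
    rows = []
    for bid, est in otree.estimates.items():
        rows.append({
            "branch": bid,
            "omega_used": _branch_value(otree, bid),
            "omega_direct": est.omega,
            "dN": est.dN,
            "dS": est.dS,
            "provenance": otree.provenance[bid],
        })
    return pd.DataFrame(rows).set_index("branch").sort_index()


def _branch_value(otree: OmegaTree, bid: str) -> float:
    ids = otree.tree.branch_ids()
    for node in otree.tree.branches():
        if ids[id(node)] == bid:
            return node.length
    raise KeyError(bid)
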