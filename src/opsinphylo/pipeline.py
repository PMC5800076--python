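"""Orchestration of the full analysis chain.

Stages mirror the study design: per-gene site-model scans (M7/M8/M8a with
both LRTs and empirical-Bayes site flags), an omega-lineage scan feeding
two-ratio branch tests with Bonferroni correction over the tests actually
run, Moran-gated ancestral reconstructions aggregated across genes, and the
orbit-convergence/activity association test. Every run can emit a
machine-readable manifest whose config hash makes deterministic stages
reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .codon_selection import (
    bonferroni_threshold,
    fit_branch_model,
    fit_site_model,
    lrt,
    site_posteriors,
)
from .omega_tree import build_omega_tree, lineage_scan, omega_tree_table
from .phylo_core import (
    PhyloError,
    parse_newick,
    read_codon_fasta,
    read_trait_table,
    write_newick,
)
from .spectral_rules import classify_trait_table
from .trait_reconstruction import (
    aggregate_across_genes,
    bm_ancestral,
    compare_mk_schemes,
    fit_mk,
    marginal_ancestral_states,
    moran_weights,
    morans_i,
    wilcoxon_ranksum,
)

logger = logging.getLogger(__name__)

CONTINUOUS_TRAITS = ("orbit_convergence", "visual_acuity")


class ConfigError(PhyloError):
    """Invalid run configuration (CLI exit code 2)."""


class ConvergenceError(PhyloError):
    """Optimizer failed to converge (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    genes: dict = field(default_factory=dict)       # gene -> alignment FASTA path
    species_tree: str | None = None                 # newick path
    trait_table: str | None = None                  # CSV path
    omega_trees: dict = field(default_factory=dict) # gene -> newick path (optional replay input)
    output_dir: str | None = None
    seed: int = 0
    alpha: float = 0.05
    K: int = 10
    n_restarts: int = 3
    outlier_threshold: float = 1.5
    branch_tests_override: int | None = None        # pin the Bonferroni denominator
    moran_comparisons_override: int | None = None
    mk_df_override: int | None = None
    marker_genes: dict = field(default_factory=dict)  # {"activity": gene, "vs_uvs": gene}
    candidate_lineages: list = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc

    def require_inputs(self, need_genes=True, need_tree=False, need_traits=False):
        if need_genes and not self.genes:
            raise ConfigError("config lists no genes")
        paths = list(self.genes.values()) + list(self.omega_trees.values())
        if need_tree:
            if not self.species_tree:
                raise ConfigError("config lists no species tree")
            paths.append(self.species_tree)
        if need_traits:
            if not self.trait_table:
                raise ConfigError("config lists no trait table")
            paths.append(self.trait_table)
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")


def _load_gene(config, gene):
    try:
        return read_codon_fasta(config.genes[gene])
    except Exception as exc:
        raise ConfigError(f"gene {gene!r} failed to load: {exc}") from exc


def _outpath(config, name):
    if config.output_dir is None:
        return None
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out / name


# ---------------------------------------------------------------------------
# Stage 1: site scan


def run_site_scan(config: RunConfig) -> pd.DataFrame:
    """M7/M8/M8a per gene, both LRTs, flagged sites at posterior > 0.75.

    Significance is marked at the nominal alpha per gene, as in the original
    site-selection tables.
    """
    config.require_inputs(need_tree=True)
    tree = parse_newick(Path(config.species_tree).read_text())
    rows = []
    for gene in config.genes:
        aln = _load_gene(config, gene)
        fits = {}
        for model in ("M7", "M8a", "M8"):
            fit = fit_site_model(
                aln, tree, model=model, K=config.K, seed=config.seed,
                n_restarts=config.n_restarts,
            )
            if not fit.converged:
                logger.warning("gene %s model %s: optimizer restarts exhausted",
                               gene, model)
            fits[model] = fit
        stat78, p78 = lrt(fits["M7"].lnL, fits["M8"].lnL, df=2)
        stat8a8, p8a8 = lrt(fits["M8a"].lnL, fits["M8"].lnL, df=1)
        # sites are assessed only when the M8 LRT is significant
        if p8a8 < config.alpha:
            _, flagged = site_posteriors(fits["M8"])
        else:
            flagged = []
        rows.append({
            "gene": gene,
            "lnL_M7": fits["M7"].lnL,
            "lnL_M8a": fits["M8a"].lnL,
            "lnL_M8": fits["M8"].lnL,
            "np_M7": fits["M7"].np,
            "np_M8a": fits["M8a"].np,
            "np_M8": fits["M8"].np,
            "LRT_M7_vs_M8": stat78,
            "df_M7_vs_M8": 2,
            "p_M7_vs_M8": p78,
            "LRT_M8a_vs_M8": stat8a8,
            "df_M8a_vs_M8": 1,
            "p_M8a_vs_M8": p8a8,
            "omega_s": fits["M8"].estimates.get("omega_s"),
            "p1": fits["M8"].estimates.get("p1"),
            "flagged_sites": ",".join(str(s + 1) for s in flagged),
            "n_flagged": len(flagged),
            "significant_at_alpha": p8a8 < config.alpha,
            "alpha": config.alpha,
            "converged": all(f.converged for f in fits.values()),
        })
    report = pd.DataFrame(rows).set_index("gene")
    path = _outpath(config, "site_scan.tsv")
    if path:
        report.to_csv(path, sep="\t")
    return report


# ---------------------------------------------------------------------------
# Stage 2: branch scan


def run_branch_scan(config: RunConfig):
    """Free-ratios omega-trees, lineage scan, two-ratio follow-ups.

    Candidate lineages come from the omega-lineage outlier scan unless
    given explicitly in the config. The Bonferroni denominator is the
    number of tests actually performed, unless pinned by
    ``branch_tests_override``. Returns (report, omega_trees dict).
    """
    config.require_inputs(need_tree=True)
    tree = parse_newick(Path(config.species_tree).read_text())
    otrees = {}
    candidates: dict[str, list[str]] = {}
    rows = []
    one_ratio_fits = {}
    for gene in config.genes:
        aln = _load_gene(config, gene)
        free = fit_branch_model(aln, tree, scheme="free_ratios",
                                seed=config.seed, n_restarts=config.n_restarts)
        otree = build_omega_tree(tree, free)
        otrees[gene] = otree
        flagged, scan_report = lineage_scan(otree, config.outlier_threshold)
        cand = config.candidate_lineages or sorted(flagged)
        candidates[gene] = cand
        one_ratio_fits[gene] = fit_branch_model(
            aln, tree, scheme="one_ratio", seed=config.seed,
            n_restarts=config.n_restarts)
        for lineage in cand:
            two = fit_branch_model(
                aln, tree, scheme="two_ratio", foreground=[lineage],
                seed=config.seed, n_restarts=config.n_restarts)
            stat, p = lrt(one_ratio_fits[gene].lnL, two.lnL, df=1)
            rows.append({
                "gene": gene,
                "lineage": lineage,
                "lnL_one_ratio": one_ratio_fits[gene].lnL,
                "lnL_two_ratio": two.lnL,
                "omega_foreground": two.estimates.get(
                    "omega_foreground", two.estimates.get("omega_background")),
                "omega_background": two.estimates.get("omega_background"),
                "LRT": stat,
                "df": 1,
                "p": p,
            })
        path = _outpath(config, f"omega_tree_{gene}.nwk")
        if path:
            path.write_text(write_newick(otree.tree) + "\n")
        tpath = _outpath(config, f"omega_branches_{gene}.tsv")
        if tpath:
            omega_tree_table(otree).to_csv(tpath, sep="\t")

    report = pd.DataFrame(rows)
    n_tests = config.branch_tests_override or max(len(report), 1)
    threshold = bonferroni_threshold(config.alpha, n_tests)
    if not report.empty:
        report["bonferroni_n"] = n_tests
        report["bonferroni_threshold"] = threshold
        report["significant"] = report["p"] < threshold
    path = _outpath(config, "branch_scan.tsv")
    if path:
        report.to_csv(path, sep="\t", index=False)
    return report, otrees


# ---------------------------------------------------------------------------
# Stage 3: ancestral reconstructions


def _load_omega_trees(config):
    otrees = {}
    for gene, path in config.omega_trees.items():
        otrees[gene] = parse_newick(Path(path).read_text())
    return otrees


def _clade_counts(tree, values):
    """Per internal node, the number of descendant tips carrying data."""
    from .trait_reconstruction import _node_ids

    tree = tree.tree if hasattr(tree, "tree") else tree
    ids = _node_ids(tree)
    counts = {}
    for node in tree.postorder():
        if node.is_tip:
            counts[id(node)] = 1 if node.label in values else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
    return {ids[id(n)]: counts[id(n)] for n in tree.postorder() if not n.is_tip}


def run_ancestral(config: RunConfig, omega_trees: dict | None = None) -> dict:
    """Moran-gated ancestral reconstructions and the activity/orbit test.

    Discrete characters are reconstructed on their designated marker genes
    (activity pattern on the RH1-analog, VS/UVS on the OPN1sw1-analog, per
    ``marker_genes``); continuous characters on every gene passing the
    Moran's I gate at the Bonferroni-corrected alpha, then aggregated
    across genes per node.
    """
    config.require_inputs(need_genes=False, need_traits=True)
    if omega_trees is None:
        if config.omega_trees:
            omega_trees = _load_omega_trees(config)
        else:
            raise ConfigError("no omega-trees supplied or configured")
    traits = read_trait_table(config.trait_table)
    df = classify_trait_table(traits)
    report: dict = {"discrete": {}, "continuous": {}, "moran": []}

    # discrete markers
    for trait_name, column, drop in (
        ("activity_pattern", "activity_pattern", ("unknown",)),
        ("vs_uvs", "vs_uvs", ("excluded", "unclassified")),
    ):
        gene = config.marker_genes.get(
            "activity" if trait_name == "activity_pattern" else "vs_uvs")
        if gene is None or gene not in omega_trees:
            continue
        otree = omega_trees[gene]
        tree = otree.tree if hasattr(otree, "tree") else otree
        states = {}
        for row in df.itertuples():
            if row.species_id not in set(tree.tip_labels):
                continue
            val = getattr(row, column)
            states[row.species_id] = None if (val in drop or pd.isna(val)) else val
        fit_sym = fit_mk(tree, states, scheme="SYM", seed=config.seed,
                         n_restarts=config.n_restarts)
        fit_ard = fit_mk(tree, states, scheme="ARD", seed=config.seed,
                         n_restarts=config.n_restarts)
        stat, p, used_df = compare_mk_schemes(fit_sym, fit_ard,
                                              config.mk_df_override)
        chosen = fit_ard if p < config.alpha else fit_sym
        recon = marginal_ancestral_states(tree, states, chosen)
        report["discrete"][trait_name] = {
            "gene": gene,
            "scheme": chosen.model.scheme,
            "LRT": stat,
            "df": used_df,
            "p": p,
            "reconstruction": recon,
        }
        path = _outpath(config, f"ancestral_{trait_name}.tsv")
        if path:
            recon.table.to_csv(path, sep="\t")

    # continuous traits, Moran-gated
    comparisons = []
    moran_results = {}
    for trait_name in CONTINUOUS_TRAITS:
        for gene, otree in omega_trees.items():
            tree = otree.tree if hasattr(otree, "tree") else otree
            values = {
                row.species_id: getattr(row, trait_name)
                for row in df.itertuples()
                if row.species_id in set(tree.tip_labels)
                and pd.notna(getattr(row, trait_name))
            }
            if len(values) < 3:
                continue
            try:
                w = moran_weights(tree, tips=sorted(values))
                series = pd.Series(values).loc[w.index]
                res = morans_i(series, w)
            except PhyloError as exc:  # constant trait, degenerate distances
                logger.warning("Moran's I unavailable for %s/%s: %s",
                               trait_name, gene, exc)
                continue
            moran_results[(trait_name, gene)] = (res, values)
            comparisons.append((trait_name, gene))

    n_comp = config.moran_comparisons_override or max(len(comparisons), 1)
    gate = bonferroni_threshold(config.alpha, n_comp)
    for trait_name in CONTINUOUS_TRAITS:
        gene_estimates, gene_p, counts = {}, {}, {}
        for (t, gene), (res, values) in moran_results.items():
            if t != trait_name:
                continue
            report["moran"].append({
                "trait": trait_name, "gene": gene, "I": res.I,
                "expected": res.expected, "variance": res.variance,
                "p": res.p_value, "threshold": gate, "n_comparisons": n_comp,
                "passed": res.p_value < gate,
            })
            gene_p[gene] = res.p_value
            if res.p_value < gate:
                otree = omega_trees[gene]
                recon = bm_ancestral(otree, values)
                gene_estimates[gene] = recon.table["estimate"].to_dict()
                counts[gene] = _clade_counts(otree, values)
        if gene_estimates:
            agg = aggregate_across_genes(gene_estimates, gene_p, gate, counts)
        else:
            agg = pd.DataFrame(columns=["mean", "sd", "n_genes"])
            agg.index.name = "node"
        report["continuous"][trait_name] = {
            "aggregate": agg,
            "n_genes_passing": len(gene_estimates),
            "threshold": gate,
            "explanation": ("" if len(gene_estimates)
                            else "no gene passed the phylogenetic-signal gate"),
        }
        path = _outpath(config, f"ancestral_{trait_name}.tsv")
        if path and len(agg):
            agg.to_csv(path, sep="\t")

    # orbit convergence vs activity pattern
    noct = df.loc[(df.activity_pattern == "nocturnal")
                  & df.orbit_convergence.notna(), "orbit_convergence"]
    diur = df.loc[(df.activity_pattern == "diurnal")
                  & df.orbit_convergence.notna(), "orbit_convergence"]
    if len(noct) and len(diur):
        stat, p = wilcoxon_ranksum(noct, diur)
        report["wilcoxon_orbit_vs_activity"] = {
            "statistic": stat, "p": p,
            "n_nocturnal": len(noct), "n_diurnal": len(diur),
        }
    path = _outpath(config, "moran_gate.tsv")
    if path and report["moran"]:
        pd.DataFrame(report["moran"]).to_csv(path, sep="\t", index=False)
    return report


# ---------------------------------------------------------------------------
# Manifest


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def manifest(config: RunConfig, stages: dict | None = None) -> dict:
    """Machine-readable provenance for a run: seed, config hash, version
    and per-stage input/output listing. Deterministic stages rerun with an
    identical manifest reproduce identical outputs."""
    return {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stages": stages or {},
    }


def verify_manifest(m: dict) -> bool:
    """Recompute the config hash; False signals tampering."""
    try:
        cfg = RunConfig(**m["config"])
    except Exception:
        return False
    return _config_hash(cfg) == m.get("config_hash")
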