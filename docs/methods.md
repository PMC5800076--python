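# Methods

This note documents the models, conventions and numerical choices behind
`opsinphylo`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Codon substitution model

The codon process is Goldman–Yang-style over the 61 sense codons of the
universal genetic code, ordered alphabetically over (A, C, G, T) triplets
with the three stops removed. For codons *i* ≠ *j*:

- q<sub>ij</sub> = 0 if *i* and *j* differ at more than one nucleotide;
- q<sub>ij</sub> = π<sub>j</sub> for a synonymous transversion;
- multiplied by κ for transitions and by ω for nonsynonymous changes;
- rows sum to zero.

κ is included even though published descriptions of the ω tests rarely
name it: the reference implementation (codeml) estimates it by default, and
omitting it biases ω. Codon frequencies default to F3x4 (products of
position-specific nucleotide frequencies estimated from the alignment, with
a 0.5 pseudocount so every sense codon remains attainable); an empirical
F61 option exists. The generator is scaled to one expected substitution per
unit time — jointly across the ω mixture for site models, per branch for
branch models — so branch lengths keep their substitutions-per-site
meaning in both directions (simulation and fitting use the same scaling
code path).

Transition probabilities use the symmetric spectral decomposition available
for reversible generators (the public `transition_probabilities` helper
uses `scipy.linalg.expm` instead, for arbitrary generators); entries below
zero by round-off are clipped and renormalized.

## Site models and their tests

M7 draws ω from Beta(p, q) on (0, 1), discretized into K equal-probability
categories represented by their exact bin means (computed from regularized
incomplete beta functions, not quadrature); K = 10 by default, matching
the conventional category count, and smaller K is used for desk-scale
calibration runs. M8 adds a class of weight p₁ with ω_s constrained to
[1, ∞), making M8a (ω_s = 1) a boundary-nested null; M8a keeps p₁ free.
LRT degrees of freedom default to free-parameter differences (2 for
M7-vs-M8, 1 for M8a-vs-M8) with an explicit override, because published
tables sometimes report df = 1 throughout. The boundary null makes the
M8a-vs-M8 test conservative at nominal levels, which the type-I acceptance
check reflects.

Positively selected sites are identified by **naive empirical Bayes at the
MLEs** (posterior ∝ class weight × class likelihood per site), not the full
Bayes empirical Bayes integration: NEB preserves the 0.75 acceptance
threshold while avoiding the prior-integration grid. This is a deliberate
simplification; NEB is known to be overconfident when parameter estimates
are poor, which matters little at the alignment sizes the package targets.
Sites are only flagged when the M8 LRT is significant and the fitted ω_s
genuinely exceeds 1 (at the boundary the extra class is neutral, and its
members are not "positively selected" no matter their posterior).

## Branch models, dN/dS bookkeeping

One-ratio, two-ratio (foreground branch set) and free-ratios models share
the site-model machinery with a single site class and per-branch ω. Branch
lengths are taken from the input tree and a single rate multiplier is
co-estimated by default; full branch-length optimization is intentionally
out of scope. Per-branch dN and dS are computed analytically from the
unit-rate generator: with ρ_N(ω) the nonsynonymous fraction of substitution
flux, dN = t·ρ_N(ω)/ρ_N(1) and dS = t·ρ_S(ω)/ρ_S(1), so dN/dS equals the
branch ω exactly. This differs in absolute scale from codeml's per-site
counting, but every downstream consumer (the ω > 10 recalculation rule and
the dN/median-dS substitution) depends only on ratios and relative dS,
which the convention preserves.

Optimization is bounded L-BFGS-B with three seeded restarts by default
(log-jittered starting points), `ftol` 1e-12; non-convergence after all
restarts is flagged on the result, never silent.

## ω-trees, lineages, outliers

Free-ratios estimates become an ω-tree: branch value = branch ω, with
branches whose ω exceeds 10 recalculated **once** as dN/median(dS over
branches with positive dS) and flagged `recalculated`; the rule is not
iterated if the substitute still exceeds 10, since the published procedure
describes a single substitution. The cutoff reading (strictly greater than
10) is exposed as a parameter. ω-lineages are root-to-tip sums; they are
standardized as (x − median)/IQR with quartiles by linear interpolation
between order statistics (numpy's default), making {1..5} map exactly to
{−1, −0.5, 0, 0.5, 1}. The default outlier threshold is 1.5 on that scale
— the box-plot convention — because the original analysis reported
"tendencies" without stating a cutoff; it is configurable. The
linearization deliberately targets terminal lineages: internal-branch
signal is diluted by construction and is not scanned.

## Ancestral reconstruction

**Discrete (Mk).** ER/SYM/ARD generators over the observed states, rates
estimated by bounded ML on the log scale, likelihood by pruning with the
ω-tree branch values as evolutionary distances — a modeling choice
inherited from the study design (ω-trees are not clocks), not endorsed.
The root prior is flat; marginal state probabilities come from a two-pass
inside/outside conditioning. SYM vs ARD is an LRT with df defaulting to the
parameter-count difference (3 for three states), overridable to 1.

**Continuous (Brownian motion).** σ² by ML; ancestral estimates in GLS
form using the tree covariance (shared root-to-MRCA path lengths); per-node
SDs include both the node's conditional variance and the uncertainty of the
GLS root. Degenerate inputs raise: zero total depth, singular covariance
(duplicate zero-length tips), fewer than two valued tips.

**Moran's I gate.** Weights are unnormalized inverse patristic distances
on the gene's ω-tree with a zero diagonal. Note that `ape::Moran.I`
row-normalizes internally, so its observed statistic differs on the same
matrix; the cross-check test feeds both implementations the row-normalized
matrix. E[I] = −1/(n−1); the variance uses the normality assumption (valid
for n ≥ 3, where the randomization variance is undefined at n = 3), and
p-values are two-sided normal approximations. Genes pass the gate at
p < α/(number of gene × trait comparisons actually run), with an override
to pin the denominator (e.g. 16) when replaying published tables.

**Aggregation.** Per node, an unweighted mean and a population SD
(divide-by-n) across genes passing the gate, excluding per gene any node
whose clade is represented by fewer than two sampled species.

**Wilcoxon.** The orbit-convergence/activity test uses the rank-sum test:
exact enumeration when the combined sample is ≤ 20 without ties, otherwise
the normal approximation with tie correction (delegated to
`scipy.stats.mannwhitneyu`; the test suite checks it against a direct
enumeration oracle).

## Spectral-tuning rules

Site 86 (bovine-rhodopsin numbering, realized by a gap-aware column map
against a reference row): F ⇒ UVS except in primates, where the rule is
known to fail and the record is left unclassified (no replacement rule is
published); Y/S/V/C/L ⇒ VS; other residues unclassified; species with an
inactive SWS1 copy excluded. Site 93 is reported as an observed
residue-by-activity contingency table (cathemeral and unknown records
tallied separately), with an optional concordance score against the field
association ({T,S,A,M} nocturnal, {P,V,C} diurnal) rather than a
hard-coded classifier.

## Synthetic data: what it emulates, what it does not

Generators produce: Yule (pure-birth) trees conditioned on the tip count;
codon alignments with i.i.d. site-class assignment evolved by exact
transition-probability sampling at branch ends (not Gillespie paths —
substitution bookkeeping, where needed, is analytic); discrete traits under
Mk chains; continuous traits by Brownian increments. Everything is
bit-reproducible given a seed, and simulation shares the generator-scaling
code with the fitters, so simulate-then-fit closes the loop for every model
family.

The synthetic data deliberately do **not** emulate: alignment error and
ambiguity patterns of real CDS data, among-site rate autocorrelation,
selection heterogeneity along branches within a site class, non-stationary
codon frequencies, or correlated trait evolution. Passing tests therefore
demonstrate statistical correctness of the machinery under its own
assumptions, not robustness to real-data violations of them.

Static fixtures transcribe printed values only: tetrapod opsin repertoire
counts (amphibians 16, reptiles 17, birds 15, mammals 10), the mammalian
ten-gene list, the bird losses (the two pineal opsins), and the human/brown
rat orbit-convergence and visual-acuity examples. The identity of the
single amphibian absence is figure-only content and is carried as a count,
not a matrix row. Genome-scale synteny discovery is out of scope and never
recomputed.

## Problem sizes in the test suite

Calibration and power checks run at desk scale, chosen once as the
package's own defaults: null-calibration runs use 5–6-tip trees with
60–150 codons and K = 3–5 beta categories (40 simulations for the
M8-vs-M8a type-I bound, 20 seeds for the M7-null and two-ratio power
checks); parameter-recovery runs keep the stated sizes (ω_s at 500 codons
and 12 tips with K = 10, reported as the median of three seeds; ER rate
and BM σ² at 100 tips over 20 seeds). The Moran-gate power scenario uses
100-tip trees because inverse-distance Moran weights have limited power on
small trees and the motivating dataset spans ~154 species. Exact-oracle
checks (pruning vs state enumeration, Mk/BM vs brute force, Wilcoxon vs
enumeration) use ≤ 4-tip trees where enumeration is feasible, at tolerance
1e-8.

## Known limitations

- NEB rather than BEB for site identification (see above).
- No branch-site models: the original analysis discarded them, and the
  package follows suit.
- The Mk and BM reconstructions inherit the ω-tree-as-distance assumption;
  results on real data should be read with that in mind.
- Free-ratios optimization is joint quasi-Newton over all branch ω values;
  on large trees this is slower and less reliable than codeml's nested
  updates, and desk-scale trees (≲ 20 tips) are the intended regime.
- The Wilcoxon exact/asymptotic switch at combined n = 20 mirrors common
  practice; near the switch, p-values from the two regimes can differ in
  the third decimal.
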