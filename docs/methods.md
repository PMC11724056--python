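# Methods

This note documents the models behind `scarscreen`, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic study

The generator (`synthdata`) emulates a neonatal skin-wound time course
with three modalities sharing one gene universe and one set of cell-class
expression profiles.

**Expression model.** Each cell class c (a major type, or a fibroblast /
macrophage subcluster) has a relative rate vector r_c over genes; class
transcript fractions are p_c = r_c / ∑_g r_cg. A cell of class c with
depth d (lognormal around `depth_mean_cells`, σ = 0.25) draws counts
NB(mean = d·p_c, dispersion α) via gamma–Poisson mixing; α = 0 degenerates
to Poisson. A single shared dispersion (`nb_dispersion`, default 0.1 —
UMI-count data is close to Poisson once depth variation is modeled) keeps
the model invertible in tests.

**Planted structure.** Every effect is a power of 2^`marker_log2fc`
(default 2.5), so `marker_log2fc = 0` yields a null generator with no
between-class fold-change:

- each major type boosts its `n_markers_per_cluster` (30) marker genes by
  2^lfc; each subcluster boosts `n_markers_per_subcluster` (8) more;
- compartment-restricted genes (the scarring genes, decoys, anchor, and
  signaling genes) are suppressed outside their home compartment by
  2^(−2.5·lfc) ≈ 1/100 — mirroring genes like *Dcn* or *Col1a1* that are
  essentially silent in immune cells. This is what makes a specificity
  threshold of τ = 0.7 meaningful on the log-normalized scale;
- the five true scarring genes are planted as strong (exponent 1.2, i.e.
  ≈ 8×) markers of specific fibroblast subclusters (*Itgbl1* peaks in F4
  with a secondary F1 peak, matching the *Col1a1* anchor's shape);
  KO-downregulation scales them (and three decoys) by
  2^`ko_downregulation_log2fc` (default −2) in knockout bulk wounds;
- one decoy per screen stage fails exactly that stage: *Fbn1* (not
  KO-down), *C4b* (fibroblast-wide but uniform across subclusters, so
  never a subcluster marker), *Ccl7* (equally strong in macrophages, so
  non-specific), *Saa3* (its wound-spot rate is flattened to ~0.8× the
  intact level, so never wound-upregulated).

**Timepoints** are three independent datasets (Days 3/7/14, no shared
cells). Fibroblast subclusters F4/F6/F8 have zero proportion on Day 3 and
appear from Day 7 — the late, repair-phase states. Major-type proportions
shift from inflammatory (neutrophil/macrophage-rich) to fibroblast- and
epithelium-rich over the course.

**Bulk** samples mix the class profiles with the Day-7 (granulation-phase)
composition; the knockout differs *only* in the scaled genes, not in
composition. This isolates the screen's arithmetic from the (real, but
confounding) compositional collapse of a myeloid-less wound.

**Spatial data** is a square lattice (25×25, 100 µm spacing) with a
circular wound disk at the center, a two-row "muscle" band, and "intact"
elsewhere. Each spot pools 20–30 cells drawn with region-conditioned type
probabilities (wound spots fibroblast/macrophage-enriched); spot counts
are sums of per-cell NB draws (gamma intensities summed, then one Poisson
draw — the variance of a true per-cell sum, not of a single NB at the
summed mean). Planted ligand/receptor genes get radial multiplicative
profiles: for `margin_to_center`, the ligand peaks on the wound-margin
annulus (r ≈ 0.85R) and the receptor at the center, each suppressed to
0.05 away from its peak (induction confined to its wound territory).

**Recorded truth** includes two flavors of per-spot composition: transcript
fractions (depth-weighted realized fractions — the estimand of any
expression-based deconvolution) and raw cell-count fractions. Recovery is
scored against transcript fractions; with equal expected depth per type
the two agree in expectation, and the depth-weighted version removes
irreducible per-spot depth noise from the comparison. The truth also
stores analytically expected wound-vs-intact log2 fold-changes and, for
wound spots, unit vectors toward the wound center (the planted signaling
direction).

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, UMI chemistry, H&E morphology, spot-boundary partial cells, and
compositional differences between genotypes. Passing tests therefore show
that the algorithms recover planted structure under idealized noise, not
that they are robust to the artifacts of real libraries.

## Single-cell stage

Normalization is log1p of counts-per-10,000. Clustering standardizes
genes, projects to the top PCs, builds a k-nearest-neighbor graph
(Euclidean, k = 15) and runs seeded Louvain. Two defaults encode the
coarse-to-fine strategy: the top-level pass uses few components
(`n_pcs = 8`) and a low resolution (0.3) so that subcluster structure does
not fragment the major types; subclustering re-runs the same recipe inside
one cluster (`n_pcs = 10`, resolution 1.0), where the restricted PCA is
dominated by within-type axes. Cluster labels are renamed by descending
size; annotation assigns each cluster the type whose canonical markers
(*Dcn*, *Lyz2*, *S100a9*, *Cd3g*, *Krt10*, *Pecam1*, *Rgs5*, *Bmp4*) have
the highest mean z-score, ties lexicographic and flagged.

Markers are one-vs-rest Wilcoxon rank-sum tests on normalized values —
exact by full enumeration of group assignments (midranks for ties) when
n₁+n₂ ≤ 16, tie-corrected normal approximation otherwise — with BH
correction within each cluster's family and the call rule q < 0.05,
log₂FC ≥ 0.585 (1.5×), pct_in ≥ 0.25. The log1p scale compresses rate
fold-changes, so planted 8× rate boosts appear as log-scale fold-changes
around 0.7–0.9; the 1.5× threshold sits below them with margin.

Fibroblast specificity of gene g is mean(g | F) / ∑_types mean(g | type)
on normalized values (pseudocount 1e-9); the screen keeps genes with
score ≥ τ = 0.7. With eight major types a uniformly expressed gene scores
0.125, a fibroblast-restricted gene ≈ 0.9, and a fibroblast/macrophage-
shared gene ≈ 0.3–0.4 — the threshold separates the planted classes with
wide margins on both sides.

## Bulk differential expression

Size factors are median-of-ratios against the geometric-mean reference
(total-count fallback if no gene is positive everywhere), normalized to
geometric mean 1. Dispersions maximize the Cox–Reid-adjusted profile
likelihood per gene on a fixed grid (0 plus 59 log-spaced points up to
~5); group means are profiled out by a short fixed-point iteration, and
the CR term −½·log ∑w per group removes the bias from estimating the mean
parameters. Raw estimates are shrunk toward a LOWESS trend of dispersion
against log mean with weight w = 0.8.

The per-gene NB GLM (intercept + KO indicator, log link, log-size-factor
offsets) is fit by IRLS vectorized across genes with a closed-form 2×2
weighted solve. The Wald statistic β̂/SE is referred to a **moderated t**
with df_resid + df_prior degrees of freedom, df_prior = df_resid·w/(1−w)
(the limma convention linking shrinkage weight and prior strength; at
n = 4 + 4 and w = 0.8 this gives t with 30 df). This combination was
chosen by simulation during method design: a plain normal Wald with
method-of-moments dispersions is anticonservative at four replicates,
while t with df_resid alone collapses power; the moderated reference keeps
the null fraction of p < 0.05 near nominal *and* the power for planted
2-fold changes high (both quantities are recomputed by the test suite and
the acceptance script rather than quoted here). Genes below the
`base_mean ≥ 1` expression floor are flagged "not tested" and excluded
from the BH family. Candidates are genes with q < 0.05 and log₂FC ≤ −1 —
DOWN in the inflammation-deficient genotype.

One caveat documented deliberately: exact invariance to scaling one
sample's counts holds only where GLM weights saturate (α·μ ≫ 1). For
near-Poisson counts, a scaled sample genuinely carries more Fisher
information and the weighted estimate moves slightly; the test asserts
invariance in the overdispersed regime the module targets.

## Spot deconvolution

The reference is each annotated type's mean raw count vector normalized to
sum 1 (counts, not log space — the mixture model is linear in counts).
For a spot with counts y, EM maximizes the multinomial log-likelihood
∑_g y_g log(∑_k w_k R_{kg}) over the simplex from a uniform start with the
multiplicative update w_k ← w_k · ∑_g (y_g/p_g) R_{kg} / N, stopping at
max|Δw| < 1e-6 or 500 iterations. The likelihood is provably nondecreasing
per iteration (asserted on stored traces), the solution matches an
exhaustive 0.01-step simplex grid search for K = 3, and weights are
invariant to gene order and count scaling. A marker-panel restriction
(union of top-50 markers per type) is available and configurable; at
300-gene desk scale the full gene universe retains more depth and is the
default in the benchmark. Zero-count spots are skipped and flagged.
Full mode only — every type may contribute to every 20–30-cell spot; no
doublet classification, no platform-effect terms.

Region DEGs compare wound vs intact spots per gene by Wilcoxon rank-sum on
log-CP10K values, BH within each timepoint's family; "spatially supported"
means q < 0.05 with positive wound log2FC.

## Communication and direction fields

The communication score for (sender i, receiver j, ligand–receptor pair)
is a Hill saturation x/(K_h + x) of x = mean(L|i)·mean(R|j) on normalized
values, K_h = 0.5: zero annihilation when either mean is zero, strictly
increasing, bounded in [0, 1). Significance is by permuting cluster labels
over cells (seeded), p = (1 + #{perm ≥ obs}) / (n_perm + 1). Pathway-level
scores take the probability union 1 − ∏(1 − s) over the pathway's pairs.
Fibroblast and macrophage cells carry their subcluster labels in this
analysis, so axes resolve to subclusters (e.g. macrophage M1 →
late-fibroblast state).

Direction fields solve entropic-regularized **balanced optimal transport**
from ligand mass to receptor mass on the spot lattice: masses are
linear-scale expression (expm1 of the log-normalized values — the log
scale would compress the induced-vs-baseline contrast that defines where
signal actually flows), each normalized to 1 over spots with signal; cost
is Euclidean distance in µm with pairs beyond `ot_cutoff_um` (500 µm)
infeasible; ε = 0.05 × median feasible cost (relative, hence invariant to
grid spacing); the Sinkhorn iteration runs in the log domain
(logsumexp-stabilized) to tolerance 1e-8 on the potentials. The sending
vector at spot s is ∑_t T_st (x_t − x_s), normalized to unit length, with
magnitude ∑_t T_st; marginal feasibility, 90° rotation equivariance and
cancellation on symmetric uniform grids are asserted directly. Spots with
zero ligand and receptor are excluded from both marginals; senders or
receivers with no feasible partner are dropped before solving.

## The screen

Stages nest by construction: final ⊆ spatially-supported ⊆
fibroblast-specific ⊆ subcluster-union ⊆ candidates, asserted on every
run. Membership requires marking ≥ 1 subcluster (with the per-subcluster
membership recorded so a stricter ≥ 2 rule can be applied downstream).
Prioritization computes each survivor's mean normalized expression across
the recovered fibroblast subclusters and ranks by Pearson correlation
with the *Col1a1* anchor profile — a deterministic surrogate for "most
characteristic of the collagen-high, late-repair fibroblast states".
Constant profiles have undefined correlation and rank last, flagged; ties
break lexicographically.

## Numerical and degenerate-input choices

- BH q-values are computed by the standard step-up with monotonization;
  q ≥ p always holds within a family.
- Pseudocounts: 1e-9 in log-fold-changes of means and the specificity
  score; 1e-300 floors inside mixture log-likelihoods.
- EM on a zero spot, markers on a < 3-cell cluster, LR pairs with absent
  genes, and empty candidate sets all warn-and-flag rather than fail; an
  empty OT problem returns an all-zero field with a warning.
- All randomness flows from explicit integer seeds (numpy Generator seed
  sequences); identical configuration implies byte-identical outputs, and
  the pipeline log records every threshold and seed used.

## Problem sizes

Defaults are desk-scale stand-ins chosen once: 1,000 genes, 3,000 cells
per timepoint (9,000 total), 625 spots per timepoint, 4 bulk replicates
per genotype. The deconvolution benchmark uses 6 types, 300 genes, 400
spots at ≈ 5,000 counts/spot; DE calibration uses 2,000 genes at 4 vs 4;
screen recovery is checked across five generator seeds in the test suite
and three in the acceptance script.

## Known limitations

- The screen's thresholds (q < 0.05, |log₂FC| cutoffs, τ = 0.7) are
  explicit, recorded choices; the original biological analyses behind this
  kind of screen used partly manual or tool-default criteria, so absolute
  gene counts per stage are not comparable — only the logic is.
- The deconvolution model omits platform effects and per-gene
  overdispersion; on real Visium/scRNA pairs those terms matter.
- Permutation p-values have resolution 1/(n_perm+1); with n_perm = 199 the
  smallest attainable p is 0.005.
- The OT direction field treats each ligand–receptor pair independently;
  competition between species and tissue-boundary-constrained costs are
  out of scope.
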