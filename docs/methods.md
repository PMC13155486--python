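# Methods

## Regulatory network and target scoring

The network links five node classes — TFs, ChIP peaks, cancer-associated
SNPs, genes, paralog groups — with directed edges TF→Peak, Peak→Gene,
SNP→Gene and Gene→ParalogGroup. Paralog groups are the connected components
of the paralog-pair relation (union-find), with deterministic ids derived
from sorted member lists; merging the internal pairs of a merged group is a
no-op (idempotence is tested). A feature→gene edge exists iff the feature
position (peak interval midpoint; SNP position as given) lies within
`window` (default 500 kb) of the gene TSS on the same chromosome.

Distance is measured as **ranked distance**: the number of genes whose TSS
is *strictly* closer to the feature than the target's TSS. Equidistant ties
do not count as closer — with coordinates on a shared integer grid, ties
are possible and the strict rule keeps the count conservative and
deterministic. Within each type (peaks of one cell line; SNPs of one
trait), features are ranked by strength (height descending, *p* ascending)
and edges by ranked distance ascending, both with competition ("min")
ranking so that "at least as highly" is the plain comparison `rank ≤ rank`.
The edge score is the fraction of same-type relationships ranking at least
as highly on both criteria; the edge counts itself, so scores lie in
[1/N, 1] and depend on the two rank vectors only (invariance under any
order-preserving transform of heights or *p*-values is property-tested).
Dominance counts use a Fenwick tree over compressed distance ranks with
equal-feature-rank blocks inserted before querying, O(N log N); a
quadratic brute force serves as the test oracle.

Query paths are matched by depth-first search against edge direction from
each candidate terminal node, pruning when the node class or an attribute
predicate fails at the current depth; matching is exhaustive over simple
paths (equivalence with brute-force enumeration is tested). The combined
target score multiplies, over the types present among the target's matched
scored edges, the minimum edge score of that type; paralog-group targets
pool the member genes' edges into the shared type groups first. Types that
contribute no edge to a target contribute no factor. Targets are ranked
ascending; ties share a competition rank.

**Permutation test.** Per round, independently for each type, the target
labels of the whole target universe are permuted, so each type's per-target
minimum-score contributions land on a uniformly random assignment of
targets; a target receiving no contribution that round has no score and
cannot count. The empirical *p* is the fraction of rounds in which the
permuted combined score is at most the observed one; the plus-one
convention ((1 + hits)/(1 + R)) avoids zero *p*-values and makes the
statistic slightly conservative, which the calibration test confirms
(super-uniform null ECDF). Tie comparison uses ≤ with a 10⁻¹² log-space
guard. Rounds are processed in vectorised batches; all randomness flows
from a single `numpy` PCG64 generator, so results are bit-reproducible
under a fixed seed.

By default only genes that appear in a paralog pair belong to a group;
`include_singleton_groups=True` adds a singleton group per ungrouped gene
so a group-terminal query ranks the entire gene universe. The end-to-end
simulations use this option.

## Peak calling from extended-read coverage

Candidate regions are maximal runs of coverage ≥ `min_overlap` (4) that
contain a position of coverage ≥ `min_height` (8), from reads extended to
the fragment length. Each region's ChIP read count is compared to the IgG
count in the same region with the Audic–Claverie comparative-count
probability — the conditional distribution of one count given the other
under a common rate, p(y|x) ∝ rʸ (x+y)! / (x! y! (1+r)^(x+y+1)) with r the
library-depth ratio — summed exactly over the complementary tail with
log-gamma terms (the identity with a negative-binomial survival function is
used as a cross-check in the tests). Regions with one-sided enrichment
p < 0.05 are reported, uncorrected, with height = maximum coverage.

## Monotone factorial model of single-cell drug responses

Counts are sum-normalised per cell and each gene's values mapped to [0, 1]
by average ranks ((rank−1)/(n−1)); a constant gene maps to 0.5 everywhere.
Ranks are computed within a cell-line pair, since models are fitted per
pair.

The cell-mean array β[g, p, d, t, c] (cell line × dose × time × phase) is
the weighted least-squares projection of the per-group means (weights =
group sizes) onto the cone of arrays monotone along d and along t — chain
constraints across all other factor levels. Both orientations of each axis
are fitted (four combinations) and the smallest residual kept; exact ties
prefer the nondecreasing direction. Empty design cells enter with weight
10⁻⁸ at the gene's grand mean, so their fitted value is interpolated by the
constraint chains without influencing the objective; residuals are computed
with true counts, so imputed cells contribute nothing.

The projection itself is computed without a general-purpose QP solver:

- single constraint family → exact weighted isotonic regression, evaluated
  row-wise in closed minimax form y_k = max_{i≤k} min_{j≥k} mean_w(x_i..x_j),
  vectorised across genes and chains (chain lengths are the handful of
  dose/time levels, so the O(L²) form is cheap and exact);
- several families (dose × time, optionally the phase-marker cone) →
  Dykstra's alternating projections, which converge to the exact projection
  onto an intersection of closed convex cones; stopping at max-change
  < 10⁻¹⁰ per cycle (500 cycles cap). Agreement with an SLSQP quadratic
  program on small grids and with PAVA (scikit-learn) on single-factor
  instances is enforced in tests to 10⁻⁶ or better.

**Phase inference.** On phase-specific marker genes (any disjoint
phase→genes map; three phases G1/S/G2M by default), the fit adds the
marker-maximality cone (the marker's fitted level is largest in its own
phase at every (p, d, t); projection by pooling on a star order). Inference
alternates (i) this constrained fit given the current phases and (ii)
reassigning each cell to the phase minimising its squared residual over the
markers. Both steps are (near-)exact minimisations, so the objective is
non-increasing — asserted each iteration with a 10⁻⁶ guard for projection
tolerance. Initial phases are uniform; 100 iterations with 10 restarts by
default, stopping early at a fixed point; the best restart by final
objective is returned. Phase labels are exchangeable, so recovery is scored
after optimal bipartite matching.

**Explanatory power and ranking.** "Rank variance analysis" is formalised
as EP_v = (RSS_reduced − RSS_full)/TSS on the rank-normalised scale, where
the reduced model collapses variable v's levels to one; EP is clipped at 0
(solver tolerance) and undefined for constant genes. The nesting inequality
RSS_full ≤ RSS_reduced is property-tested. The drug ranking score is
EP_drug in the sensitive cells minus EP_drug in the resistant cells of the
same pair, fitted on the respective subsets, descending. A
sensitive-conditional score with a resistant filter would be an easy
variant but the difference is the default, as it directly encodes
"responds in sensitive, not in resistant".

## CGE fitness statistics

Tags are kept when both day-2 counts reach the cutoff (5–50 depending on
depth; values outside that band warn). The per-tag statistic is the double
ratio log2[(mut_d8/restored_d8)/(mut_d2/restored_d2)] — mutant-versus-
restored first, then time — which cancels sequencing depth (tested) and is
antisymmetric under allele swap (tested). Zero day-8 counts get a 0.5
pseudocount on all four counts of the affected tag (Haldane), flagged;
dropping such tags is available as an alternative policy. The site-level
test is the two-sided Wilcoxon signed-rank against zero: exact null
distribution for n ≤ 25 when magnitudes are distinct and nonzero, otherwise
the normal approximation with continuity correction and tie-corrected
variance. An all-zero ratio vector is degenerate (p = 1, flagged).

## Set-level contrasts

Within each cell-line pair, replicate measurements collapse by median to a
per-feature contrast: treated − control in the sensitive line, or the
difference of the sensitive and resistant deltas ("difference" mode, the
drug-specificity contrast). Missing features stay missing. Per set and
pair, the unweighted mean over observed member contrasts is taken
(duplicate set entries count once); sets whose median observed size falls
below 3 are excluded — the threshold keeps at least a usable df while
letting sparse acquisition through, and is configurable. The unit of
replication is the cell-line pair: a two-sided one-sample *t*-test across
pairs, Benjamini–Hochberg adjusted (via statsmodels), with a 1% FDR flag.
Zero-variance sets are flagged rather than given p = 0.

## Synthetic data

The generators emulate the statistical shape of the real inputs, not their
sequencing substrate; all are deterministic under a fixed seed.

- **Annotation**: genes uniform over a 100-Mb, 5-chromosome genome with
  unique TSSs; paralog pairs partly chained (30%) to exercise transitive
  merging.
- **Peaks**: background peaks uniform at 5 /Mb per (TF, cell line) track —
  the density of a typical real ChIP track scaled to the synthetic genome —
  with geometric heights (p = 0.3); planted master genes receive one peak
  per track within 5 kb of the TSS whose height is the background draw plus
  a boost of 20, making planted peaks top-ranked on both criteria with high
  probability.
- **SNPs**: 500 background SNPs per trait with log₁₀ p uniform on [−8, −5]
  (GWAS-catalog-like); planted loci near planted TSSs with log₁₀ p on
  [−12, −9], strictly below the background range.
- **Single-cell counts**: negative binomial (dispersion 0.2, mean depth
  5000 per cell) over a full (pair × status × dose × time) design. Planted
  drug genes follow a scaled logistic in the ordinal dose and time level —
  smooth, saturating, direction-controllable, like real dose responses —
  with log2 amplitude 1.5 at the extreme condition, in sensitive cells
  only. Phases are drawn uniformly; marker genes are elevated four-fold in
  their own phase and recorded in the ground truth. Not emulated: library-
  size variation beyond NB noise, doublets, ambient RNA, batch effects, or
  dose-dependent phase composition — so passing recovery tests shows the
  estimator works under its own assumptions, not that real data meet them.
- **CGE counts**: multinomial sampling at fixed total depth of lognormal
  tag abundances; day-8 mutant weights scaled by 2^(s·n_doublings), so the
  expected per-tag log2 ratio has the closed form s·n.
- **Fold changes**: Gaussian noise around the planted per-set shift
  (constant across pairs), with optional uniform missingness mimicking
  data-dependent acquisition.

## Problem sizes

The recovery simulations (shared by the test suite and
`scripts/acceptance.py`) use: 500 genes / 60 paralog pairs / 5 cancer types
× 3 TFs / 3 planted groups with 10⁴ permutation rounds; 1000 null networks
of 20 exchangeable targets × 3 types at 10³ rounds for calibration; 2
cell-line pairs × 3 doses × 3 times × 200 cells per condition with 20
planted genes of 500 for the single-cell model; 200 tags at depth 10⁴ for
CGE; and 100 simulations of 50 sets × 10 features over 8 pairs (shift 0.5,
noise 0.2) for the set-level FDR. These sizes make each planted effect
clearly detectable while keeping a full run on one CPU in the minutes
range.

## Known limitations

- Edge scoring is quadratic in memory-free form but the network builder
  itself iterates rows in Python; build time, not scoring, dominates for
  >10⁵ features.
- The permutation null permutes target labels per type independently; it
  does not preserve spatial autocorrelation of peaks along the genome, so
  neighbouring genes of a true target can share its signal (visible in the
  worked example).
- Dykstra projections are exact only in the limit; tolerances (10⁻¹⁰
  per-cycle change) make residual constraint violations negligible relative
  to the rank-normalised data scale but not identically zero.
- The phase-inference objective is non-convex in the joint (β, C)
  variables; restarts mitigate but do not guarantee the global optimum.
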