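# Methods

## The alignment model

A reference lineage is a non-branching differentiation trajectory: an
expression matrix with a per-cell pseudotime in [0, 1] (construction of the
reference pseudotime itself — integration, diffusion maps — is upstream of
this package; the pseudotime table is an input). Counts are normalized per
cell to a fixed library size of 10^4 and log1p-transformed; the scale is a
convention, and every downstream correlation is invariant to it.

Cycling cells are flagged by a G2M program score (mean lognorm of the G2M
gene set minus the mean of expression-matched control genes, via scanpy's
scoring routine) with the cutoff fixed at 0.1, strict inequality. Cycling
cells never receive a pseudotime: a cycling cell's transcriptome is
dominated by cell-cycle programs orthogonal to the lineage axis, and the
alignment is restricted to the non-branching trajectory.

Non-cycling reference cells are binned into `n_bins` (default 50)
equal-width pseudotime bins; bins with fewer than 10 cells are dropped
(an error below 5 surviving bins). A query cell's **similarity profile** is
its Pearson correlation, over the trajectory genes, with each bin's mean
expression vector. Profiles are then shape-normalized per cell (mean 0,
variance 1), so only the profile's shape — where along pseudotime the cell
resembles the reference — carries information, not its overall correlation
level. Constant profiles (or constant cells) are flagged degenerate.

Pseudotime is predicted from the normalized profile by a 3-layer perceptron
(input = number of retained bins, two hidden layers, scalar output, lbfgs
solver). Training data are the reference's own profiles with
**self-masking**: each cell is removed from its own bin's mean before
correlating, preventing the target from leaking through the profile.
Hyperparameters are chosen by 5-fold cross-validated mean squared error
over a compact grid (hidden sizes (32, 16) and (64, 32), L2 penalty 1e-3);
the grid is deliberately small — the problem is low-dimensional and the
two candidates already span the relevant capacity range — and fully
configurable via `param_grid`. The winner is refit on all profiles.
Predictions are clipped to [0, 1]. All fits are deterministic given the
seed.

Out-of-distribution cells are flagged from the raw profile: maximum
correlation below `c_min` = 0.2, or peak prominence (max minus median)
below 0.05. These defaults are calibrated for trajectory sets at the
method's typical scale (roughly 150-250 genes); the noise floor of a
correlation over G genes scales as 1/sqrt(G), so much smaller gene sets
warrant a higher `c_min`.

Stages follow the printed pseudotime cutoffs: Dormant below 0.141, Q below
0.282, A on the closed interval [0.282, 0.676], D above. Dormant is a
sub-label of Q: compositions count it as Q. Compositions are fractions over
aligned cells (plus cycling as a fourth category when requested);
out-of-distribution and degenerate cells are excluded from the denominator.
Compositions are compared by the Aitchison distance (Euclidean distance of
centered-log-ratio transforms, zeros replaced by a pseudofraction of 1e-3
and renormalized).

## Alignment QC by DTW permutation

If an alignment is faithful, binning the query along its aligned pseudotime
reproduces the reference's expression dynamics, and the ref-bin x query-bin
correlation matrix shows a narrow high diagonal. The test statistic is the
mean correlation along the monotone path (moves: down, right, diagonal)
that **maximizes the mean** correlation. The mean rather than the sum is
maximized because paths differ in length — a sum objective would favor long
staircase paths whenever correlations are positive. The max-mean path is
found by Dinkelbach's parametric method: repeated max-sum dynamic programs
on the matrix shifted by the current mean estimate, converging to the
optimal ratio; exact ties prefer the diagonal move, so a constant matrix
yields the plain diagonal. Path length and diagonal deviation are reported
as secondary diagnostics.

The null distribution comes from **expression-matched gene permutations**:
genes are binned into expression deciles by their mean lognorm in the
non-cycling reference, and each permutation samples a non-trajectory gene
set preserving the trajectory set's decile histogram. Each permutation
reruns the entire pipeline — reference binning over the permuted genes,
self-masked profiles, perceptron retraining at the hyperparameters chosen
for the observed run (no grid re-search; the grid winner is a property of
the profile dimensionality, not of the gene set), query prediction, query
binning, DTW. The P-value uses the add-one rule,
p = (1 + #{permuted >= observed}) / (1 + n_perm), so p is never 0 and is
bounded below by 1/(n_perm + 1). A permutation whose query binning
collapses (fewer than 5 populated bins) scores the correlation minimum of
-1 rather than being resampled, so degenerate permutations cannot inflate
significance. Because the observed statistic is computed by the identical
routine, observed and permuted runs are exchangeable under the null; the
suite verifies that null P-values are approximately uniform.

The **pseudotime coherence** statistic (for comparing any pseudotime
methods on equal footing) is the Pearson correlation between pairwise cell
distances in a 10-component PCA space and pairwise pseudotime *rank*
distances; ranks make it invariant to monotone reparametrization.

## Trajectory gene derivation

Given Q/A/D stage labels on the reference, trajectory genes are derived by:
(1) prefilter — detected in at least 1% of cells and mean expression in
some stage at least 1.5x the mean of the remaining cells; (2) recursive
feature elimination with a random-forest stage classifier on a 70/30
split (3-fold cross-validation scores the retained set), active only when
the prefiltered pool exceeds the target size; (3) repeated random-subset
importance: 500 draws of 500 genes, a random forest per draw, mean
importance per gene across the draws in which it was sampled; (4) knee cut
on the ranked importances — applied to the **log** curve, because forest
importances separate signal from noise multiplicatively and the log exposes
that cliff where the linear curve's knee would land inside the smoothly
decaying signal range; (5) ribosomal genes (symbols matching ^RP[LS],
case-insensitive) removed; (6) at most 100 genes per stage, each gene
assigned to the stage of its maximum mean expression.

Stage boundaries can also be detected from data: a Gaussian KDE (Scott's
rule) over the non-cycling pseudotimes on a 1001-point grid; with three or
more density modes, boundaries sit at the density minima between the first
three peaks (fewer modes is an error that points to the printed defaults).

## Expression dynamics and EMD

A gene's dynamics in a sample are summarized on a pseudotime grid of step
0.05. Cells are grouped into the grid's 20 bins; bins under 20 cells are
discarded (at least 3 must survive). A spline with 5 cubic B-spline basis
functions on [0, 1] is fit to the bin means with an L2 penalty (weight 1.0
by default) on the integrated squared second derivative; the penalty Gram
matrix is computed exactly by Gauss-Legendre quadrature per knot interval.
Five basis functions deliberately cap the curve's flexibility at the scale
of a stage; the penalty weight trades bias for variance and is exposed in
the API. Fitted values are clipped at 0 and area-normalized by the Simpson
rule into a unit-area density.

The Earth Mover's (Wasserstein-1) distance between two such densities on
[0, 1] is computed exactly from the grid CDFs (scipy's implementation);
it is bounded by 1, translation of a fixed shape by d gives distance d up
to grid resolution, and area normalization makes it invariant to overall
expression level. If either gene-sample curve is unexpressed (zero area)
the distance is 1 — lost expression is maximally dysregulated by
convention, including the both-unexpressed case.

The healthy reference curve per gene averages the *unit-area* curves of the
expressed healthy samples and renormalizes, weighting each sample equally
regardless of absolute expression. Recurrent dysregulation ranks genes by
mean EMD to the healthy curve across tumors, after three filters: genes in
the upper half of healthy spline area (area-normalization amplifies noise
in lowly expressed genes), genes lost in at most half the tumors, and
exclusion of the trajectory genes themselves (they define the alignment).
The dysregulated set is everything ranked above the kneedle inflection of
the descending mean-EMD curve (no knee means no calls, with a warning).

Group biomarker analysis compares two tumor groups per gene: each member's
EMD to its group mean curve (within-group consistency), discarding genes
above 0.1 in either group, then ranking survivors by the EMD between the
two group means. The area-difference ratio compares a healthy and a
diseased curve per pseudotime increment (early/middle/late thirds by
default): Simpson area of the absolute difference in the increment divided
by the maximum value of either curve, plus the least-squares slope of the
ratios across increments — positive slope means divergence grows along
pseudotime.

## The QAD population model

States (Q, A, D) evolve by d(Q,A,D)/dt = M (Q,A,D) with

    M = [[-r_act,        2 p_self r_div,              0      ],
         [ r_act,        (2 p_amp - 1) r_div,         0      ],
         [ 0,            2 (1-p_self-p_amp) r_div,   -r_death]]

from division outcomes Q+Q (p_self), A+A (p_amp), D+D (otherwise), Q→A
activation, and D loss. `r_div` is pinned to 1 and defines the time unit.
M is Metzler (nonnegative off-diagonal), so states stay nonnegative, the
dominant eigenvalue is real and gives the asymptotic exponential growth
rate, and its nonnegative eigenvector (normalized to sum 1) is the
equilibrium stage composition. The system is isolated behind
`build_model_matrix` so an alternative linear model is a one-function swap.

Propagation uses the matrix exponential — exact for a linear system.
`tE` is the first time the total-variation distance of the stage
proportions to equilibrium drops below 0.01 *and stays below* (guarding
against transient dips); `tD` solves total(t) = 10^11 cells (undefined
without positive growth).

Fitting to an observed (Q, A, D) composition minimizes the Aitchison
distance between the model equilibrium and the observation over (r_act,
p_self, p_amp, r_death), multi-start L-BFGS-B (25 starts by default) with
a smooth penalty keeping p_self + p_amp inside the simplex. A 3-part
composition has two degrees of freedom against four parameters, so the fit
is a representative parameterization, not a unique one: diagnostics report
the residual (flagged non-converged above 0.05), and a multimodality flag
when near-optimal starts disagree by more than 0.05 in any parameter.
Growth rates across a cohort are regressed on log activation rate
(ordinary least squares), reporting R² and flagging high-residual tumors —
candidates for compensation through other parameters such as self-renewal.
The early-equilibrium property (tE/tD small) is asserted in the fitted
regime — parameters obtained by fitting observed compositions — not over
the unconstrained parameter box, where slow-activation/high-amplification
corners violate it.

## Synthetic data: what it emulates, and what it does not

The generator produces a non-branching lineage with uniform (or
stage-weighted) pseudotime; informative genes follow Gaussian-bump programs
(centers spread over [0, 1], widths 0.08-0.18, amplitude 4, baseline 0.2),
background genes are flat with baselines drawn uniformly up to `noise_base`
(default 3.0) so they span the expression range — a requirement for
expression-matched permutation sets to exist at every decile, as in real
data. Counts are negative-binomial (dispersion theta = 10) around the
program means scaled by log-normal library sizes (sd 0.3). Cycling cells
(10% by default) add a G2M program; out-of-distribution cells resample
every gene independently from the in-distribution marginal; query samples
reweight stage composition, and dysregulated genes shift their bump center
(default +0.3) in queries only — always the same informative,
non-trajectory genes, so dysregulation is recurrent across a cohort.

Defaults mirror the scale the alignment is validated at: a 2,000-cell,
300-gene reference with 150 trajectory genes and 500-cell queries. The
permutation and cohort analyses use deliberately scaled-down conditions
chosen once: permutation tests on a 300-cell/600-gene/60-trajectory-gene
reference with 15 bins and 150-cell queries (a small trajectory fraction
keeps decile matching feasible); the dysregulation cohort uses 3 healthy
samples (800 cells, balanced composition) against 10 tumors (800 cells)
along a Q-dominated to D-dominated spectrum, with 20 planted genes of
amplitude 6 over a 0.8-max background so the plant sits in the clearly
expressed regime the upper-half-area filter targets.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, branching lineages, cross-species ortholog mismatch, or biological
covariation among background genes. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated noise
model — not robustness to the full messiness of real tumor data.

## Numerical conventions

- Pseudotime rescaling: a reference lineage rescales its non-cycling
  pseudotimes to span [0, 1] exactly.
- Stage boundary conventions: A is closed, [0.282, 0.676]; dormant is
  strict, pt < 0.141; cycling is strict, score > 0.1.
- Degenerate inputs: constant cells/profiles are flagged, never silently
  normalized; all-zero cells are an error naming the cell; constant
  pseudotime is an error for coherence; an all-linear ranked curve has no
  knee (returns null).
- Determinism: every stochastic step (scoring controls, forests,
  perceptrons, permutations, the generator, multi-start fits) is driven by
  an explicit seed and is bit-reproducible.
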