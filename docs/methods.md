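# Methods

## Count model and overdispersion estimation

Counts are modeled per gene as X_ij ~ NB(mu_j, gamma_j) with
E[X] = mu and Var(X) = mu + mu^2/gamma; gamma -> infinity recovers the
Poisson. The estimator (`velostab.dispersion`) is an intercept-only
Gamma-Poisson fit: the mean is profiled out as the per-gene sample mean and
the shape is maximized by bounded 1-D optimization in log gamma
(Brent, xatol 1e-8 on the log scale), with the likelihood evaluated on the
distinct observed counts weighted by multiplicity so sparse columns cost
O(#distinct values) per likelihood call. Spliced and unspliced layers are
fitted independently.

Conventions for degenerate genes, chosen to be explicit and testable:

- all-zero gene: the likelihood is flat in gamma at mu = 0, so the gene gets
  the Poisson sentinel (`inf`) and mu_hat = 0;
- sample variance <= sample mean: no overdispersion is detectable by the
  method-of-moments screen, Poisson sentinel;
- optimizer at the upper search bound (default interval [1e-3, 1e6]): the
  likelihood keeps improving toward the Poisson limit, so the sentinel is
  reported instead of a numerically meaningless large shape.

Identifiability caveat: when gamma >> mu the NB variance exceeds the Poisson
variance by only mu/gamma relative, and no estimator resolves gamma well.
At mu = 1, gamma = 10 even a fine grid-search MLE lands within 15% of the
truth in only about two-thirds of 10 000-cell replicates; the test suite
asserts tight recovery only where the information supports it, plus
agreement with an independent grid-search oracle everywhere.

## Count splitting

Each entry x is divided by the two-category Dirichlet-multinomial with both
parameters gamma_hat_j / 2, realized exactly as p ~ Beta(g/2, g/2) followed
by x1 ~ Binomial(x, p), x2 = x - x1 (O(1) per nonzero entry; zero entries
are untouched and sparse storage is preserved). Under the true shapes the
splits are independent and each is marginally NB(mu/2, gamma/2); with the
Poisson sentinel the draw degenerates to Binomial(x, 1/2). Plug-in
estimated shapes induce a slight dependence between splits; empirically the
cross-split per-gene correlations stay inside the +/-1.96/sqrt(n) band for
well over 90% of genes, which is the regime the framework needs.

Randomness discipline: every (layer, gene) pair draws from its own
`SeedSequence(master_seed, spawn_key=(layer, gene))` substream, so results
are independent of iteration order, stable under adding genes or layers,
and bit-reproducible from the master seed.

## Built-in steady-state velocity estimator

The framework treats the velocity method as a black box behind a plugin
contract (`fit(spliced, unspliced) -> VelocityResult`). The built-in
estimator implements the classic first-order model for testability:

1. library-size normalize each layer to a fixed per-cell total (1e4), which
   makes the output invariant to uniform depth changes;
2. smooth both layers by kNN means (k = 30, self included) on the top 30
   principal components of the log1p-normalized spliced layer;
3. per gene, fit the steady-state ratio g_j by least squares through the
   origin of smoothed u on smoothed s, restricted to cells in the extreme
   quantiles of s (default 0.05 at each tail, the cells presumed nearest
   kinetic equilibrium); genes whose extreme cells are all zero fall back
   to all cells, genes with no spliced signal are dropped;
4. velocity v_ij = u~_ij - g_j s~_ij.

A `RandomVelocity` negative control emits isotropic Gaussian vectors; its
replicate coherence centers at zero and its signal-to-random score hovers
near zero, which the tests and the acceptance script verify. Latent-space
methods can be compared by projecting both splits' gene-space velocities
onto one shared orthonormal basis computed from the full, unsplit data;
cosine similarities are preserved exactly when the vectors lie in the basis
span.

## Coherence metrics

Replicate coherence is the *uncentered* cosine between a cell's two
velocity vectors, one per split, computed over the sorted union of genes
retained in either split with zeros filled in — genes selected in only one
split contribute to the norms and thus penalize the coherence. Local
coherence first centers each cell's vector by its across-gene mean and then
averages the cosine to its neighbors; the centering asymmetry between the
two metrics is deliberate and follows their respective definitions. The
neighbor graph (k = 30 on 30 PCs by default) is computed once from the
full, unsplit spliced matrix so both splits share one neighborhood
structure.

Degenerate cells: a zero-norm (or, for local coherence, constant-across-
genes) vector has no direction; such cells get a NaN sentinel and are
excluded from medians and means. A cell with some zero-norm neighbors is
averaged over the informative neighbors only; it becomes NaN only when the
cell itself, or every neighbor, is degenerate.

The shuffled-pair null permutes the cell rows of one split's velocities and
recomputes the per-permutation median coherence; element 0 of the returned
array is the observed (identity-pairing) median so observed and null are
always on the same footing.

## Matched control genes and the signal-to-random score

Three matching features per gene — spliced zero-fraction, unspliced
zero-fraction, and the steady-state R^2 (1 - SS_res/SS_tot of the
through-origin fit on smoothed layers; negative values are kept as-is) —
are each cut into four equal-count bins, giving 64 possible groups.
Quartile rather than equal-width bins make the matching robust to the
heavily skewed sparsity distributions of scRNA-seq. For each informative
gene (visited ratio times in seeded-shuffled order, which avoids
input-order depletion bias), one control is drawn uniformly from the
eligible genes of its own bin, falling back to the nearest non-empty bin by
Euclidean distance on the integer bin coordinates, ties broken uniformly at
random. The control set is twice the informative size by default — small
control sets tend to fall below velocity preprocessing thresholds in
practice. A shortage of eligible candidates is an error that reports the
deficit.

The score over B seeded runs (each: fresh split, fresh control draw, two
velocity fits per gene set) is the Welch-style statistic with sample
variances (denominator B - 1). It is reported as a selection heuristic, not
a p-value. Seeds failing inside any component are excluded with a warning
and the effective B is reported. Per-seed component seeds are derived as
`SeedSequence(master_seed, spawn_key=(b, *component_name_bytes))`, so adding
components never perturbs existing streams.

Seed-robustness diagnostics correlate the per-cell coherence vectors of all
B(B-1)/2 seed pairs (cells non-missing in both), test positivity one-sided,
and Bonferroni-correct by the number of evaluated pairs. An uncentered
variant (sum xy / sqrt(sum x^2 sum y^2)) is available behind a flag. The
missing-cell-type experiment drops one labeled group of cells, keeps the
gene universe fixed (genes may become all-zero), and compares coherence
summaries before and after.

## Synthetic data generator

Each kinetic gene follows du/dt = alpha - beta u, ds/dt = beta u -
gamma_ss s, solved in closed form from u(0) = s(0) = 0: induction up to a
switch at t = 0.6 of the unit latent-time interval, then repression
(alpha = 0) continuing from the switch state. The beta = gamma_ss
degeneracy is handled by the analytic limit (the (e^-gt - e^-bt)/(g - b)
term becomes t e^-gt), keeping the solution continuous; closed forms are
verified against a Runge-Kutta integration to 1e-6 in the tests. Ground
truth velocity is beta u - gamma_ss s.

Defaults, sized for quick iteration: 500 cells with latent times uniform on
[0, 1]; 100 kinetic genes with per-gene rates drawn log-uniform
(alpha in [1, 4], beta in [0.8, 3], gamma_ss in [0.3, 1.5], spanning slow
to fast kinetics at order-one scale); 200 noise genes; NB shapes log-uniform
on [1, 20] (the overdispersion range typical of UMI data); per-cell library
factors log-normal(0, 0.3); means scaled by 20 so counts land in the
single-digit-to-tens range of real spliced layers. Counts are drawn
NB(library_i * mean_ij, gamma_j) with independent substreams per layer.

Noise genes reuse kinetic mean profiles with the cell order permuted
independently per gene: their sparsity and u-vs-s relation (hence R^2)
resemble kinetic genes — exactly the confounders the control matching
adjusts for — but they carry no coordinated trajectory, so a method should
be less stable on them. Stage labels are latent-time terciles by rank
(early/mid/late), supporting the missing-cell-type experiment.

What the generator does not emulate: branching or cyclic trajectories,
cell-cycle confounding, ambient RNA, doublets, gene-gene correlation beyond
the shared trajectory, or batch structure. Passing tests therefore
demonstrate correctness of the machinery and sensible behavior under the NB
trajectory model, not performance on arbitrary real tissues.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at desk scale —
500-cell default datasets, 2000 x 200 split-marginal checks, 1e5-draw
Monte-Carlo closed-form checks, B = 5 with 10 master seeds for the
end-to-end control — sizes at which every Monte-Carlo tolerance asserted is
several standard errors wide while the full run stays in the tens of
seconds. Gene order after union alignment is lexicographic; TSV reports
print floats as %.10g with literal `NA`/`inf` sentinels so identical
records re-serialize byte-identically. Counts loaded from containers are
validated as integers (floats within 1e-6 of an integer are rounded,
anything else rejected) to guard against accidentally splitting normalized
matrices.

## Limitations

- The NB assumption is per-gene with a constant shape; strong mean-variance
  departures (e.g. zero inflation beyond NB) bias gamma_hat downward and
  weaken the independence guarantee of the splits.
- Estimated (not true) shapes are plugged into the split, so exact
  independence is not guaranteed; the induced correlation is small in
  practice but not zero.
- The built-in steady-state estimator is intentionally simple (shared
  smoothing graph, through-origin fit); it exercises the framework and is
  not a substitute for a production velocity method.
- The signal-to-random score depends on the user's informative gene set;
  with a poorly chosen set the score compares two noise sets and loses
  meaning.
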