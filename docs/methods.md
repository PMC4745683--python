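# Methods

## The kinetic model

Each transcript's concentration x(t) (non-log intensity units) is assumed to
follow first-order production/degradation kinetics driven by a hidden,
shared regulator activity f(t):

    dx/dt = B + S·f(t) − D·x

with per-transcript basal production B (intensity/h), sensitivity S
(intensity/h), degradation rate D (1/h), and f dimensionless. On the
sampled grid the derivative is replaced by a linear operator A, so the
model solution is the linear system

    (A + D·I)·x = B·1 + S·f .

The first row of A is zero: the net rate of change is taken to be nil at
the moment the stimulus is applied, which pins x(0) = B/D. This also means
D = 0 leaves the system singular (A annihilates constant vectors), so the
optimizer's lower bound on D is 1e-3/h.

After a transcription arrest (actinomycin-D chase), production ceases and
the level decays as x_d(τ) = x_d0·exp(−D·τ). The chase is modelled by this
continuous closed form rather than a second discrete operator because the
chase grid (0, 1, 2, 5.5 h) is short and unequally spaced. x_d0 is a free
parameter rather than being pinned to the measured τ = 0 value, so the
τ = 0 residual remains informative.

### The derivative operator

For the default seven-point expression grid (0–21 h, 3.5 h apart) the
operator is a fixed rational stencil. Rows 4, 5 and 7 are the standard
five-point central and three-point backward difference formulas for 3.5 h
spacing and are exact for linear trends (verified by exact fraction
arithmetic in the tests); rows 2, 3 and 6 are smoothed early/late-time
estimators that trade a small linear-trend bias for noise damping, and are
implemented verbatim rather than "corrected". All rows sum to zero, so the
operator annihilates constants exactly. For any other grid, three-point
Lagrange-interpolation derivative stencils are generated over the local
nodes (central in the interior, backward at the last point), with the
first row zeroed.

### Compound production

G = dx/dt + D·x ≈ A·x + D·x is the per-gene production rate. Under the
model G = B + S·f, an affine transform of the hidden activity, so min-max
normalized G profiles averaged within a cluster visualize that cluster's
driving activity. For a constant series G ≡ D·x, and a G profile whose
range is numerically zero (below 1e-12 relative to its magnitude) is
treated as degenerate and skipped.

## Pair fitting and the RSS dissimilarity

For a transcript pair, both genes' expression series (7 points each) and
chase series (4 points each) are predicted from gene-specific (B, S, D,
x_d0) and one shared f, giving 22 residuals, each divided by the data
point's standard deviation. The residual sum of squares is minimized by
bounded nonlinear least squares (scipy's trust-region reflective method,
the bound-respecting relative of Levenberg–Marquardt), from several
deterministic starts (default 3).

Identifiability: f's scale is degenerate with S and its offset with B. The
convention adopted is f(0) = 0 (structural: the first activity value is
not a parameter) and max f = 1, imposed by renormalizing after convergence
and absorbing the scale into S; the RSS is unchanged by this rescaling.

Initialization: D starts at the empirical log-linear decay estimate of the
chase series; B at D·x(0); x_d0 at the observed chase start; f at the
min-clipped, normalized compound production of one of the two genes (the
first two starts use gene 1 and gene 2 respectively, further starts are
multiplicative jitters). Bounds: B, S, x_d0 in [0, 10 × max observed
intensity]; D in [1e-3, 5]/h; f values in [0, 2] before renormalization.

Determinism: each pair's start jitter derives from a seed hashed from the
sorted gene-id pair plus the global seed, so the full matrix is identical
regardless of execution order, chunking, thread count, or whether a run
was resumed from a checkpoint. The pair is internally canonicalized to
lexicographic order, making the (A,B)/(B,A) symmetry exact.

The minimized RSS is the dissimilarity between genes: it is small when one
activity profile can drive both genes' expression *and* chase data, and
large otherwise — in particular for genes whose expression profiles are
similar only because different activities are filtered through different
decay rates. Absolute RSS values depend on the error model and optimizer
settings, so only their ordering is meaningful across analyses.

### Error model

When replicate standard deviations are unavailable, sd = a + b·intensity
with defaults a = 1 intensity unit and b = 0.1 (a 10% CV floor at high
intensity, consistent with multiplicative log-normal noise at CV = b).
Both are configurable and applied identically to expression and chase
matrices.

## Gene selection

The modelled (up-regulated) set requires, per gene: expression range
(max − min) ≥ 1.5 intensity units; up-regulation strictly above 1.5-fold
relative to time zero at some point; and never dropping below 10% of the
time-zero value. The ">" is strict for up-regulation thresholds and
inclusive ("≥") for down-regulation (at least 1.5-fold dip), following the
convention that "more than" is strict and "at least" is inclusive. The
floor fraction is configurable: a stricter reading of "not significantly
down-regulated" could raise it toward 2/3. The range threshold is in
non-log intensity units (the same scale the matrices carry); a log-scale
reading is available by flagging log2 input in the configuration, which
exponentiates on load.

## Degradation-array normalization

After an actinomycin-D arrest, total RNA falls, so total-intensity
normalization would bias decay rates toward zero. Arrays are instead
rescaled against the quartile of slowest-decaying transcripts, iterating:
scale by current factors → refit per-gene log-linear decay → re-define the
stable quartile → re-center each array so the stable set's median
log-ratio to the τ = 0 array is zero; stop when no factor moves by more
than 1e-3 (max 50 iterations). The τ = 0 factor is pinned to 1. The
procedure is deterministic, invariant to gene order and to a global
rescaling of all arrays. The stable-set fraction (0.25) and tolerance are
configurable. This scheme is this package's own concrete definition of
iterative stability-reference normalization — a reimplementation choice,
not a reproduction of any published procedure.

Empirical decay rates are ordinary least squares of log x on τ, clamped at
zero (D̂ = max(0, −slope)); they are used for initialization, QC and the
G-profile computation, while pair fitting re-estimates D jointly with
everything else.

## Clustering

**Principal activities.** Ward's minimum-variance agglomeration is applied
to d = √RSS (Lance–Williams update on the provided distances, scipy's
`linkage(..., "ward")`; an alternative variant applies the update treating
the distances as already squared, matching older hclust ward.D semantics).
The dendrogram is cut into k = 5 clusters; the two-branch top split is
also reported. Cluster labels are ordered by the time at which the
cluster's mean normalized G profile first reaches half its maximum
(earliest = 1), so labels read as a temporal sequence. Tie-breaking is
deterministic: genes are sorted lexicographically before linkage.

**Down-regulation waves.** Genes down-regulated ≥ 1.5-fold are clustered
by Pearson correlation of their raw profiles: average linkage on 1 − r cut
at height 1 − 0.8, with clusters smaller than 5 genes reported as
unassigned; a connected-components-at-r ≥ 0.8 mode is available. Waves are
numbered by the time of steepest decline of their mean min-max-normalized
profile.

**Transcription factors.** Intersection with a user-supplied symbol list
is case-insensitive and exact otherwise; per-cluster counts are reported.

## Constrained ordination

Two reference populations (start/end differentiation states, ≥ 2
replicates each) define a per-gene gradient: the top-N genes (default
2000) by empirical-Bayes moderated-t p-value, carrying the end-minus-start
mean log2 intensity (so end-state-high genes are positive; the t statistic
itself is a configurable alternative).

The moderated t shrinks each gene's pooled variance toward a prior:
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) estimated by moment
matching on the distribution of log sample variances (the trigamma
equation is inverted by Newton iteration); p-values use d₀ + d_g degrees
of freedom and Benjamini–Hochberg adjustment. Homogeneous variances drive
d₀ → ∞, in which case every gene uses the pooled prior and the statistic
is Gaussian. The implementation reproduces the standard limma-style
estimator to machine precision (checked during development; the in-repo
tests verify the closed-form posterior identity instead).

Sample scoring treats the gene × sample intensity table as a contingency
table: with P the table normalized to total 1 and r, c the row/column
masses, the χ²-standardized residuals Q = Dr^(−1/2)(P − rcᵀ)Dc^(−1/2) are
projected onto the row-mass-weighted, centred gradient variable, and the
rank-1 projection is decomposed by SVD. Sample scores are the axis-1
column principal coordinates, oriented so the last sample scores at least
as high as the first; constrained inertia is the squared singular value
and total inertia the sum of squared standardized residuals (constrained ≤
total always, with equality only when samples vary solely along the
gradient). Genes are rows ("sites" carrying the environmental variable)
and samples columns, because the goal is a per-sample score along a gene
gradient; a transposed convention would score genes instead. Per-gene
contributions to the axis are |row score| × row mass, and the top-M
contributors (default 1000) are exportable. The implementation agrees with
R's vegan `cca` on toy tables (development check) and with an independent
eigen-decomposition route in the test suite.

## Synthetic data

The generator emulates the study design so every stage is testable without
any external download: 7 expression arrays 0–21 h; 4 chase arrays at
0/1/2/5.5 h after an arrest at 10 h; 60 up-regulated genes driven by five
activity shapes (early maintained, early short, early intermediate, late
continuous, late short — all with f(0) = 0, max 1, pairwise Pearson
r < 0.95); 30 down-regulated genes as sigmoid declines with midpoints
3.5/10.5/17.5 h; 30 unchanged genes; decay half-lives log-uniform on
0.5–20 h; baselines log-uniform on 50–500 intensity units; sensitivity 1.5–5×
basal production (rejection-sampled per gene until the noise-free profile
passes the three modelled-set rules); multiplicative log-normal noise at
CV = 10% with mean one; optional per-array loss factors on the chase
arrays to exercise normalization.

Chase series are produced by continuous-time RK4 integration of the ODE to
the arrest time (activity linearly interpolated between grid points), then
exact exponential decay — data the discrete model only approximates, as
with real measurements. A `model_exact` mode generates from the discrete
equation instead, for zero-residual tests. Reference populations are 2000
genes × 3 replicates per group with a 5% planted differential fraction at
3 replicate-sd log2 shifts; the scored trajectory interpolates
geometrically between the group means.

The cohort sizes (60/30/30) keep the full pairwise fit (1770 pairs) at
roughly two minutes on one CPU, which is what makes routine end-to-end
testing practical. What passing tests on this generator do **not** show:
robustness to probe-level artifacts, batch effects, non-multiplicative
noise, cell-population mixtures, or activities outside the five planted
shapes; and with 12 genes per activity the clustering recovery bounds are
looser than they would be at study scale.

## Numerical choices and limitations

- Optimizer: ftol = xtol = gtol = 1e-12, max 600 residual evaluations per
  start, 3 starts; `x_scale` set per parameter block so intensities and
  rates are comparably scaled.
- RSS matrices must be symmetric with zero diagonal; √RSS is taken
  entry-wise with no jitter, and Ward merge heights are checked monotone.
- Zero or negative values: genes with non-positive chase values are
  excluded from log-linear decay fits; zero-sum rows/columns are dropped
  (with warnings) before ordination; zero-variance genes are excluded from
  correlation clustering.
- The pairwise stage scales as n(n−1)/2: a 3375-gene cohort means
  5,693,625 fits, which is cluster-scale work; `--max-genes` subsamples
  deterministically for desk-scale runs and warns that cluster-level
  results will differ.
- Joint fitting is limited to pairs; no attempt is made to fit one shared
  activity to larger groups, to smooth f in continuous time, or to place
  posteriors on parameters.
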