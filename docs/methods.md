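# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, a
brain-age analysis built on resting-state functional connectomes: network
construction, cross-subject principal components, lifespan trajectory
models, three feature constructions, three age regressors with internal and
external validation, and a permutation test for predictive edges.  This
note records the models, the generator's assumptions, the numerical
choices, and what the synthetic results do and do not show.

## Connectome construction

Per subject, node time series are band-pass filtered (0.01–0.1 Hz,
4th-order Butterworth, forward–backward) before Pearson correlation;
correlations are Fisher-transformed, z = atanh(r), with |r| clipped at
1 − 1e-7 so unit correlations stay finite.  The canonical edge order is
row-major over 0-based pairs (i, j), i < j; the cohort edge matrix **D**
(edges × subjects) stacks each subject's upper triangle.  The
*multi-subject matrix* is the Fisher-z correlation of all subjects' series
concatenated in time, after z-scoring each node within subject so subjects
with different variances contribute equally.

fALFF is computed on the *unfiltered* series (filtering first would fix the
ratio by construction): the series is linearly detrended, tapered with a
Hann window (a single-taper periodogram — without the taper, spectral
leakage from off-bin components moves several percent of amplitude across
the band edge), and the ratio of amplitude-spectrum sums in 0.01–0.1 Hz
over 0.01–0.25 Hz is formed.  A bin belongs to a band when its center
frequency lies in the closed interval.  A `spectrum="power"` switch sums
power instead of amplitude.  For slow acquisitions whose Nyquist frequency
is below 0.25 Hz (TR = 2.5 s gives 0.2 Hz) the estimator refuses the
nominal band; the pipeline caps the total band at min(0.25 Hz, Nyquist)
and reports the band used.

## Cross-subject PCA

The decomposition operates on the raw, uncentered **D**: **P** holds the
eigenvectors of **DᵀD** sorted by descending eigenvalue, **T = DP**,
explained variance is each eigenvalue over their total, and subject *i*'s
matrix is reconstructed as Σⱼ p<sub>ij</sub>T<sub>j</sub> (devectorized,
unit diagonal).  Uncentered PCA is deliberate: with a strong shared
baseline the leading component is essentially the mean connectivity
pattern, which is exactly why it reproduces the multi-subject matrix; a
`centering="edge_mean"` option exists.  Eigenvector signs are fixed so the
component most correlated with age (when ages are supplied) correlates
positively, and otherwise so each coefficient column's largest-magnitude
entry is positive.  Out-of-sample coefficients are least-squares
projections onto the fitted components — by orthogonality,
T<sub>j</sub>ᵀd / ‖T<sub>j</sub>‖², which reproduces training coefficients
exactly.

## Lifespan models

Each unit y (edge z, network summary, or node fALFF) is fit with OLS:

    y = b0 + b1·age + b2·sex + b3·FD + b4·TIV + e
    y = b0 + b1·ac + b2·ac² + b3·sex + b4·FD + b5·TIV + e,  ac = age − mean(age)

Centering age before squaring controls collinearity; covariates are left in
natural units.  Significance requires *both* the overall-fit F-test p and
the age-term t-test p to survive Benjamini–Hochberg correction at q within
the family (all units of one level and model type — edges-linear,
edges-quadratic, networks, nodes are separate families).  Classes follow
the sign of the surviving age term (increase/decrease, U/inverted-U), with
the quadratic class taking precedence when both survive (configurable).
The mass-univariate fits are vectorized linear algebra (one solve for all
units); they agree with statsmodels per-unit fits to 1e-10 in tests.
Within(X) is the mean z over pairs inside network X, Between(X, Y) the mean
over crossing pairs, and WithinBetween(X) = Within(X) − mean over Y≠X of
Between(X, Y) — a per-network segregation index.

## Feature constructions and leakage

*Network features* are the first L (default 150) component coefficients.
*Edge features* use the supervised covariance-maximizing reduction: after
standardizing edges X and ages Y on the training set, p₁ = XᵀY/‖XᵀY‖ (the
closed-form maximizer of Cov(Xp, Y) under ‖p‖ = 1), u₁ = Xp₁, X and Y are
deflated by their regressions on u₁, and the step iterates l times.  The
depth l is chosen by inner cross-validation over {5, 10, 20, 40} on the
reduction's own predictions unless fixed.  *Temporal features* are node
fALFF values.  All three obey a strict fit(train)/transform(any) contract;
`leakage_mode="paper"` optionally fits the feature step once on the whole
cohort (the optimistic protocol suggested by fitting reducers before
cross-validation), which the test suite shows inflates cross-validated r
dramatically for the supervised reduction (ages enter its fit) and not
measurably for the unsupervised PCA features.

## Prediction

OLS, Lasso ((1/2n)‖y − b0 − Xb‖² + λ‖b‖₁), and ε-insensitive SVR, via
scikit-learn; the linear SVR kernel uses the primal solver (LinearSVR),
which fits the same loss orders of magnitude faster than libsvm at large C.
Penalized families standardize features internally.  λ is searched on a
15-point log grid anchored at the data-driven λ_max (the smallest penalty
zeroing all coefficients); SVR searches kernels {linear, rbf, poly-3} ×
C ∈ {1, 10, 100}; all hyperparameters are chosen by seeded inner
cross-validation on MAE using training subjects only.  K-fold validation
(default K = 10) uses a seeded shuffle into near-equal folds; pooled
metrics over all held-out predictions are primary, per-fold means are
reported alongside.  External validation applies the internally fitted
feature pipeline and model unchanged.  Accompanying statistics: Pearson r
and MAE (years); Steiger's z for two dependent correlations sharing the
age variable; a pooled-variance two-sample z on absolute errors by group;
and the correlation of absolute error with age with
t = r√((n−2)/(1−r²)).

## Edge significance

A model that is linear in the reduced components is linear in the
standardized edges; the per-edge weight composes the component coefficients
with the loading/deflation chain (ρ_k = Π_{j<k}(I − p_j c_jᵀ) p_k).  The
permutation null shuffles ages, refits the reduction (ages enter it, so the
null must break that path) and the model with hyperparameters frozen at the
real-fit values, and uses add-one two-tailed p-values
(count + 1)/(B + 1) ∈ [1/(B+1), 1].  Null calibration and super-uniformity
are verified against binomial and DKW bounds in the tests.

At desk scale the pipeline tests weights through the *leading* component
only (l = 1): with deeper reductions the later components fit residual
noise in real and permuted data alike, inflating every edge's null and
collapsing power (at n = 200, p = 50: 54/61 planted edges detected at l = 1
vs at most 1 at l = 10).  Likewise the pipeline's default level is a
two-tailed 0.01 with B = 1000: at this n even planted edges bottom out near
p ≈ 0.002, so the full-study level of 0.001 with B = 10,000 (kept as the
`PermutationConfig` default) has no power here.

## Synthetic cohorts

The generator emulates the statistical regime every stage assumes; the
underlying study is empirical and prescribes no generative model, so all
generator choices are stand-ins, made once and documented here.

Subject *i*'s target z-matrix is Z_i = B + (a_i − ā)A + C(a_i − ā)² + E_i:
a block baseline B (within-network z = 0.45, between 0.08, edge jitter
sd 0.04), a sparse linear age pattern A (5% of edges at ±0.004 z/yr, two
thirds negative, mirroring predominant age-related decline), sparse
quadratic curvature (1% of edges at ±1.5e-4 z/yr², mostly inverted-U), and
symmetric Gaussian subject noise (sd 0.03 z).  B is itself projected to a
valid correlation matrix with eigenvalue floor 0.15 when the ground truth
is built, so per-subject projections (eigenvalue clipping at 1e-8 plus
diagonal renormalization) are rarely active — an active projection shrinks
planted effects, and at these defaults the planted-slope recovery ratio is
0.99–1.00.  Targets are mapped to correlations by tanh, projected, and
realized by coloring Gaussian noise with the symmetric matrix square root.

Each node's series mixes a band-limited (0.01–0.1 Hz) and a broadband
component, x = √w·low + √(1−w)·broad, with w solved per node and subject by
monotone bisection so the expected amplitude-spectrum fALFF equals the
target falff_base + slope·(a − ā) (+ quadratic on listed nodes + subject
noise sd 0.04, clipped into the attainable range; the attainable floor is
the flat-spectrum ratio, ≈0.375 at TR 0.645 s).  Both components are
colored with the *same* correlation factor: imposing correlation on the
broadband part only would attenuate realized correlations by roughly the
broadband weight, whereas with equal per-node weights the shared coloring
preserves the targets exactly, both broadband and after band-pass (small
distortions arise only where w differs across nodes).  Defaults: 70% of
nodes at −8e-4 fALFF/yr, 10% at +5e-4, four U-shaped nodes at +2e-5/yr²
(the quadratic magnitude is deliberately marginal at n = 200).

Covariates: ages uniform on 6–85 y (the study samples the lifespan without
a stated density); sex Bernoulli(1/2); FD lognormal with 0.2 age
correlation; TIV normal (1350 cm³, sd 110) with a +10% offset for sex = 1.
Covariates do not enter the connectivity targets, so the lifespan models'
covariate terms estimate true zeros.

The default paired cohorts scale the study's two protocols down while
preserving their scan-duration ratio: internal n = 200, 600 volumes at
TR 0.645 s (387 s); external n = 80, 160 volumes at TR 2.5 s (400 s).  The
external cohort additionally carries elevated subject noise (z-noise 0.08,
fALFF noise 0.08) standing in for the site/protocol/sample differences that
degrade external validation; without some cross-cohort shift, external
validation is *not* harder than internal in simulation.

What passing tests show: every algorithmic step is correct against
closed-form, brute-force, or library oracles, and the full protocol
recovers planted intrinsic structure, age components, trajectory classes,
and predictive edges at realistic noise.  What they do not show: behavior
under real BOLD phenomena the generator omits — motion artifacts and
scrubbing, non-Gaussian noise, spatially structured confounds, scanner
drift, genuine covariate-connectivity coupling, or dynamic (non-stationary)
connectivity.

## Numerical details

Problem sizes in the test suite and acceptance script (200/80 subjects, 50
nodes, 600/160 volumes, B ≤ 1000 permutations) are the package's default
desk-scale study conditions.  Fisher clipping 1e-7; PSD eigenvalue floor
1e-8 (baseline construction 0.15); supervised-reduction early stop at
relative covariance 1e-12 with a warning flag; eigenvalue ties broken by
the solver's stable ordering plus the sign rule; degenerate (zero-variance)
edges contribute nothing to PCA, are dropped with record by the supervised
reduction, and yield flagged zero correlations in the age-effect matrix;
constant predictions make Pearson r undefined and are reported as NaN
rather than an error inside cross-validation.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; reruns are
byte-identical.
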