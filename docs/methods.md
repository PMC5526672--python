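# Methods

This note documents the models and estimators implemented in `flywalk`,
the synthetic data used to validate them, and the numerical choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Body-frame kinematics

A trajectory is a centroid `(x, y)` in cm and a head direction `theta`
in degrees on a uniform 30 Hz grid (other rates are supported; spacing
must be uniform to 1 ns). Orientation is unwrapped modulo 360° before
any smoothing or differentiation. Positions and unwrapped orientation
are smoothed with a Gaussian kernel, s.d. 1 frame by default (FWHM
≈ 0.08 s at 30 Hz).

Velocities use central differences at interior samples; the two
endpoints are dropped. The lab-frame centroid velocity is projected on
the instantaneous body axes: `vT` along the heading unit vector
`(cos θ, sin θ)` and `vS` along the leftward perpendicular
`(−sin θ, cos θ)`. Conventions fixed here (the field uses both signs):

* rotation counterclockwise-positive, in deg/s;
* side-slip positive toward the animal's left, so that a fragment's
  `c·vS` preserves slip direction *relative to the turn*.

Accelerations are `np.gradient` per component (central interior,
one-sided endpoints). The heading velocity is
`vH = vR − d/dt arctan2(vS, vT)` in deg/s; the two-argument arctangent
keeps the slip angle defined when `vT` crosses zero, and `vH` is
NaN-masked where the planar speed is ~0 (heading of motion undefined;
fragment assembly substitutes `vR` there, since a non-translating
animal's heading change is its body rotation).

## Kinematic field and effective counts

The field bins `(vT, vR, vS)` on a regular grid (defaults
`|vR| < 450°/s` by 25, `−0.6 ≤ vT ≤ 3.2` cm/s by 0.09,
`|vS| < 0.94` cm/s by 0.063, all configurable) and stores per bin the
mean acceleration vector and the mean absolute deviation
`E[|v̇ − ⟨v̇⟩|]` (vector norm — a conservative dispersion measure).
Because consecutive samples are autocorrelated, the effective count per
bin divides the raw count by the dataset-level integrated
autocorrelation time `τ_int = 1 + 2 Σ ρ̂_k` (initial-positive-sequence
truncation; standard and bias-bounded), averaged over the three
components. Bins below `n_eff = 10` are masked. A per-bin
autocorrelation estimate would be noisier than the quantity it
corrects, which is why a single dataset-level factor is used.

Note a subtlety verified in the tests: for a reversible noise-driven
process, the *central-difference* acceleration conditioned on the
current velocity has zero expected drift (forward and backward
increments cancel); the drift-recovery oracle therefore uses smooth
relaxation trajectories with observation noise.

## Divergence statistic

`σ̄(t)` is the product of the per-component standard deviations of the
trajectory ensemble `t` seconds after passing a small velocity
neighborhood, normalized by the stationary per-component deviations and
averaged over `NB = 200` randomly sampled neighborhoods (without
replacement among occupied bins). Neighborhoods are single occupied
bins of the kinematic grid. A *passage* is a bin entry: consecutive
samples inside one bin count once. Conditioning schemes: none; a `vR`
extremum a fixed delay (default 100 ms) after the neighborhood; that
plus the peak's mode label. Neighborhoods with fewer than 5 surviving
passages (configurable) are skipped and counted. The 95% CI comes from
50 repeats of the neighborhood draw.

Small ensembles bias each sample s.d. low, and the three-component
product cubes that bias; each s.d. is therefore divided by the Gaussian
`c₄(m)` factor. With this correction the statistic matches the
three-component Ornstein–Uhlenbeck closed form
`σ̄(t) ≈ (1 − e^{−2t/τ})^{3/2}` within the CI and reaches ≈ 1 at
decorrelation. σ_t is pooled over a neighborhood's entry times (the
per-entry-time alternative discards most of the data at this scale).

## Iterative-ICA segmentation

Fragments are windows around local `|vR|` extrema (extrema of either
sign, window ±2 frames = ±83 ms, plateau ties to the earliest sample).
Support is ±300 ms (19 samples at 30 Hz; ±550 ms → 33 samples is
available but the outer samples carry little variance). Fragments
without full support are dropped. Each fragment is sign-normalized by
`c = sgn vR(0)`, multiplying `vR` and `vS` (and `vH`) by `c`, making all
central turns positive while preserving relative slip.

Per tree node: the fragments' components are stacked row-wise
(component × t′), each row standardized (stored mean/s.d. are reused at
classification time), the matrix whitened by PCA and reduced to the
smallest PC count reaching the variance threshold — 85% at the root,
90% deeper, capped at 6 PCs (5–6 components suffice for these data and
keep the ICA search well-conditioned). The root uses the `(vH, vT)`
representation (38 rows): folding the correlated `vR` and `vS` into one
rotational variable helps ICA converge on the full heterogeneous set.
Deeper nodes use all of `(vR, vT, vS)`.

Whitening uses `D^{−1/2}` in `E D^{−1/2} Eᵀ` — the only exponent
consistent with the identity-covariance contract.

FastICA (kurtosis-family contrast, `fun="cube"`) runs from 10 random
initial demixing matrices. A component is *stable* when a majority of
restarts reproduce it up to sign/permutation (matched |corr| > 0.95)
and its coefficient kurtosis exceeds the sampling floor
`max(0.1, 5·√(24/N))`; with no stable component the node reports
non-convergence (a status, not an exception — isotropic Gaussian data
lands here by construction).

**Multimodality detection.** The original procedure separated coefficient
clusters by visual inspection; here the criterion is explicit: a 1-D
coefficient distribution splits when a 2-component Gaussian mixture
beats 1 component by ΔBIC > 20 *and* the mixture density has a valley
between the component means at most 0.7× the lower peak (the split
boundary is the density minimum; a 6-s.d.-separated balanced mixture is
cut within 0.5 s.d. of the midpoint). Splits whose minor component is
small (< 0.25) with ≥ 3× the spread are flagged as tail-type. If no 1-D
feature separates, 2-D component pairs are tested (GMM ΔBIC plus a
centroid-separation criterion) and cut by pairwise k-means. Optional
rotated 1-D projections of pairs and per-node force/forbid overrides
are exposed in the config. A non-ICA fallback split on the joint peak
velocity `(vT(0), vR(0))` distribution is available for nodes where ICA
does not converge but the joint distribution shows two tails.

Termination: non-convergence, stable ICs that merely reproduce the PC
axes, no separable feature, or a child below the minimum leaf size.
Exceeding the depth cap raises an error carrying the partial tree.
Leaves (submodes) are numbered in deterministic DFS order; the catalog
(transforms + split rules) serializes to versioned JSON and routes new
fragments identically — classification is invariant to turn mirroring
by construction, since mirrored fragments have identical sign-normalized
arrays.

Segmentation may split one planted movement pattern into more than one
pure leaf (e.g. by transition context at short inter-peak gaps); this
is the expected behavior of a splitting-biased first stage — grouping
into modes happens downstream from transition statistics. The
planted-template recovery tests (exactly K leaves, ARI > 0.9 for
K ∈ {2, 3, 5} at 10⁴ fragments and ≥ 4 noise-s.d. separation) use
directly sampled fragments; the end-to-end test (detect → segment →
classify on rendered trajectories) uses two maximally distinct
patterns, ~0.6 s mean gaps and ±0.2 s windows so that fragments are
dominated by a single pattern.

## Sequence models

`ρ` and `ρ₂` are plug-in (maximum-likelihood) estimates pooled over
sequences, with percentile CIs from 1000 bootstrap resamples over
trajectories (the independent unit). No bias correction is applied: at
the pooled sizes used the plug-in MI bias `O(M²/2N ln 2)` is well below
the reported effects, and the i.i.d. test asserts exactly this bound.
Order-k chains (k ≤ 2) are count-based; unseen contexts fall back to
the marginal and are flagged.

HMMs are categorical-emission models trained by EM (hmmlearn) from 15
random restarts — uniform-then-normalized random matrices, a random
training subset of 1500 sequences per restart — keeping the restart
with the best training likelihood (all restart likelihoods retained).
EM satisfies the row-sum constraints by construction; acceptance is by
likelihood and planted-model recovery, not optimizer identity.

A mode model (MM) groups submodes into modes: its transition matrix is
the row-normalized grouped joint-transition count matrix, and each
mode's emission row holds within-group relative frequencies, so
emission columns have exactly one nonzero. (The printed sum-of-
conditionals form of the grouped transition estimate is only
row-stochastic for singleton source groups; the count-based ML estimate
is used, which reduces to it in that case.) Parameter counts:
`N(N−1)+N(M−1)` (HMM) versus `N(N−1)+(M−N)` (MM, requiring `M ≥ N`);
with a single state the two coincide. Transition probabilities below
≈ 0.005 are flagged as below the sampling resolution of the measured
rates. The MM log-likelihood conditions the start on the stationary
distribution of the mode chain.

Stationarity is checked two ways: a chi-square contingency test of
symbol frequencies between early and late data halves (split at the
median symbol time), and the total-variation distance between the
empirical marginal and the model's equilibrium symbol distribution.

## Match statistic

Fixed-length sequence sets are compared as multisets:
`ν_{X∩Y}(x) = min(ν_X, ν_Y)`,
`F_R:R = (1/|R|) Σ_r ν_{R∩R′}(r)`, `F_S:R = (1/|R|) Σ_s ν_{S∩R}(s)`,
and `f = ⟨F_S:R⟩_N / ⟨F_R:R⟩_N`. `f` is symmetric under alphabet
relabeling and invariant to duplicating both pools (both tested).

Two protocols are implemented, honoring each context. The held-out
generative test draws 11 disjoint sets of 5000 length-5 real
subsequences, never reusing a source sequence, compares set 1 with the
other 10 for `⟨F_R:R⟩`, and with model-generated sets for `⟨F_S:R⟩`.
The length-resolved curve `f(k)`, `k = 2…20`, samples with replacement
(`|R| = |S| = 500`, `N = 5000` draws by default) from pools of real
length-k subsequences — one random window per source sequence, because
overlapping windows of one trajectory are strongly correlated and
inflate real–real matches. Durations map `k` to seconds through the
empirical mean span of the real windows; model-generated sequences use
a constant 167 ms per step (the modal inter-peak interval). `τ_P` is
the largest duration with `f ≥ 0.9`, linearly interpolated.

A structural property worth noting: with replacement-sampling from a
finite pool, `F_R:R` contains pool-identity collisions (`≈ |R|²/pool`)
that `F_S:R` lacks, so even the true generator's `f` falls below 1 once
distributional matches decay beneath that floor. The truth-recovery
tests therefore use a repetitive chain and k ≤ 10, where distributional
matches dominate; this is a property of the protocol, not of any
implementation choice.

The sequence-frequency comparison pools all k-windows, generates a
model pool of matched size, and drops sequences whose real frequency is
below `½(2.58/√N)²` — the frequency whose 99% normal-approximation CI
reaches zero (the cutoff formula is exposed in config; the exact
parenthesization used elsewhere for this cutoff is ambiguous, and this
reading makes it a proper sampling-error floor, monotone in N).
Pearson correlation is reported on retained log-frequency pairs present
in both pools.

## Profiles and dwell times

A velocity profile is the per-t′ joint histogram of `(vT, vR, vS)` on a
configurable grid (the kinematic grid, coarsenable, by default) plus
the central 68% band (P16–P84) per component and time point. The
Bhattacharyya coefficient is computed on the joint `(v, t′)`
distribution with uniform t′ weight — equivalently the mean over t′ of
per-t′ overlaps, which are also exposed; B is symmetric and invariant
under common bin permutations (property-tested). Significance:
fragments of the two groups are pooled and re-split at the original
sizes 10 000 times; `p` is the fraction of null overlaps at or below
the observed one, with `p < 0.002` significant at the 0.05 level under
Bonferroni correction for the 25 mode-pair comparisons. The null
calibration (uniform p under identical generators) and the 1-s.d.-shift
power test are part of the suite.

Dwell time in a mode is the span between the first and last `vR`
extrema of an uninterrupted run; runs touching a sequence edge are
censored and excluded, and single-extremum runs count as dwell 0 under
this convention (the extended variant adds half-gaps to the neighboring
extrema and gives them positive dwell). Model-generated sequences use
the fixed 167 ms time base. Exponential fits are ML (`λ̂ = 1/mean`,
zeros shifted by half the smallest positive sample so the density is
defined); the two-component option is an EM exponential mixture from 5
restarts, with `2Δlogl` against the single fit as the misfit
diagnostic. A second, long-dwell stop component — the
non-communicating extra stop state — is representable as exactly this
two-component fit.

## Synthetic data: what it emulates, and what not

The generator is the ground truth for every stage. Defaults are the
study conditions: a first-order Markov chain over five modes with the
measured transition rates (rows renormalized from their printed
4-decimal values), inter-peak intervals Gamma(shape 3, scale 1/12 s) —
mean 250 ms, modal value ≈ 167 ms — trajectory lengths shifted-geometric
with mean 3.3 peaks (the short-trajectory dataset; long-arena-like
protocols pass a larger mean), 30 Hz sampling, and per-mode template
curves over ±300 ms whose `vR` extremum sits at t′ = 0. Templates are
parametric caricatures (stop, sharp turn with forward acceleration,
slow side-slip, slow straight run, fast run/smooth turn); their exact
shapes are free parameters of the generator, not measured profiles.
Turn direction is mirrored at random per peak. Velocities are template
means, held over each template's support and cross-faded linearly over
the uncovered middle of each inter-peak gap (transitions live between
peaks), plus Gaussian noise whose temporal correlation is exposed as an
AR(1) parameter (default white — real within-mode noise correlation is
not constrained by the data). The first state of every chain is drawn
from the stationary distribution. All randomness flows from one seed.

What the generator does **not** emulate: biomechanical gait structure,
arena-boundary effects, inter-individual variability, slow
non-stationarity, or the empirical continuum of fragment shapes within
a mode (templates are discrete). Passing tests therefore show that the
estimators recover the structure they assume, at realistic sizes and
noise — not that real data satisfy those assumptions.

## Problem sizes

Test and acceptance runs use deliberately moderate sizes chosen for
stable statistics: 10⁴ fragments for segmentation recovery, 2–4·10³
sequences for dependence statistics, 2.5·10⁴ sequences and
`N = 400–1000` draws for match curves, 600-member ensembles for the
OU divergence check, 10³ fragments per group with 2·10³ bootstrap
resamples for profile power. Each quantity's sampling error at these
sizes is well inside the asserted tolerances.
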