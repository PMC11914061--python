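# Methods

## The lineage-fate model

Each simulated cell is independent (the model is asynchronous; there is no
tissue geometry or cell–cell coupling beyond the neighbour *count*). One
generation per cell:

1. **Mother initialisation.** Birth size ~ gamma(shape, scale) µm², rounded
   to the nearest integer µm² and floored at 1; SPCH intensity ~ normal
   (negative draws re-drawn, since fluorescence is non-negative); signaling
   neighbours ~ Poisson. One parameter set per individual plant.
2. **Asymmetric division.** The asymmetry a = 1 − SLGC/mother is drawn from
   a beta distribution, perturbed by a uniform ±0.5 noise factor, and
   rejected back into (0, 0.5) so the SLGC is always the larger daughter.
   The SLGC size is `round(mother · (1 − a))`, clamped to
   [1, mother − 1] so both daughters have positive integer area; the
   meristemoid takes the exact remainder (conservation holds by
   construction). The SLGC inherits two-thirds of the mother's SPCH
   intensity and one extra signaling neighbour (its new sister
   meristemoid). Nuclear area comes from the allometric map with residual
   noise on.
3. **SPCH degradation.** A decay-constant magnitude |λ| (per hour) is drawn
   from an exponential distribution selected by the degradation mode:
   pooled (`random`), per neighbour class {1, 2+} (`neighbour`), per-µm²
   scaled by cell area (`size`), or per-µm² per class
   (`neighbour_and_size`). λ = −|λ|, so intensity at the dip
   (`I₀ e^{λ·t_dip/60}`, t_dip = 200 min by default) never exceeds birth
   intensity. [SPCH] at the dip is intensity over nuclear area.
4. **Fate.** P(divide) = logistic(intercept + Σ coefficient·feature), with
   features drawn from {size, [SPCH] at dip, neighbours} and optional
   pairwise interactions; fate is a single Bernoulli draw, and the
   probability is stored.

### Noise factor on the asymmetry

A "uniformly distributed ±0.5 noise factor" on the asymmetry is ambiguous:
an additive U(−0.5, 0.5) term routinely leaves the unit interval. The
default here is a multiplicative factor U(0.5, 1.5) ("factor" reads
multiplicative), followed by reject-and-redraw until a ∈ (0, 0.5); an
additive variant is available via `noise_mode="additive"`, and
`noise_mode="off"` disables it. Rejection (rather than clamping) keeps the
SLGC the larger daughter by definition and avoids a point mass at the
boundary.

### Degradation duration

How long decay runs before the fate readout is a free choice; the default
fixes it at the dip time of 200 min (configurable `t_dip_min`), rather than
drawing per-cell dip times, so that the dip state is a deterministic
function of (I₀, λ, nuclear area) and the latent table fully determines it.

## Input-distribution fitting

`fit_input_distributions` takes a per-SLGC cohort table that carries the
mother-level quantities alongside each cell (mother size, mother intensity,
mother neighbour count, asymmetry, λ). Fits are maximum likelihood: gamma
via the standard MLE with location fixed at zero, normal via sample
moments, Poisson via the mean, asymmetry via a truncated-beta MLE on
(0, 0.5) (Nelder–Mead on the log-shape parameters), exponentials via the
mean of |λ| over declining cells. Rising cells (λ > 0) are excluded from
the exponential fits — the distribution is supported on the positives —
but are retained and flagged by `fit_decay`; exclusion decisions belong to
callers. Per-µm² magnitudes are |λ|/area of the same cells.

Two caveats, both deliberate:

- With the asymmetry noise factor on, the realised asymmetry is not a
  truncated beta, so the fitted (a, b) describe the *effective*
  distribution; exact parameter recovery (loop closure within sampling
  error) is guaranteed — and tested — with the noise factor off.
- λ fitted from trajectories absorbs the photobleaching trend (~1.8 %/h
  against mean biological declines of 23–42 %/h), exactly as in real
  imaging; loop-closure tests therefore recover the decay distributions
  from the latent true λ, and the bleaching rate has its own estimator.

## Measurements

- **Allometry.** OLS of ln(nuclear area) on ln(cell area); σ_ε uses the
  n − 2 denominator. The built-in calibration (β = 0.19, α = 1.82,
  σ_ε = 0.027, with σ interpreted as a standard deviation, the R
  convention) is used wherever nuclear area must be imputed.
- **Decay.** Log-linear OLS of ln(intensity) on time in hours over a
  0–200 min window by default. Deterministic, initialisation-free, and
  exact on noiseless data, unlike nonlinear least squares; zero-intensity
  samples are dropped with a warning count.
- **Dip.** Centred moving average (default width 3, shrinking at the
  edges), then the global minimum of the smoothed series within a 0–400 min
  search window; ties go to the earliest time.
- **Bleaching.** Pooled OLS of intensity on hours over all nuclei;
  rate = −100·slope/intercept (%/h).
- **Contact fraction.** `0.5(P_SLGC + P_nb − P_union)/P_SLGC`; values
  outside [0, 1] by more than 1e-9 are clamped with a warning, never
  silently.

## The classifier

CART with Gini impurity, grown to purity (or a minimum leaf size), split
thresholds at midpoints of adjacent sorted unique values with `<=` routing
at equality. Weakest-link pruning records the distinct effective alphas
g(t) = (R(t) − R(T_t))/(|leaves| − 1) on the Gini risk scale; subtree
selection maximises accuracy on a seeded 70:30 held-out split (unstratified
random sampling without replacement), breaking ties toward the larger alpha
(smaller tree). A class tie at a leaf predicts ACD. Forest importances fit
bootstrap-resampled trees with √d feature subsampling per split and report
each feature's summed sample-weighted impurity decrease, normalised to
sum to 1. The pruning path is parity-tested against scikit-learn by running
this implementation's pruner on the reference's own grown tree (grown trees
can legitimately differ through split tie-breaking).

## Model selection

- **TOST bound.** "One standard deviation" is taken from the *reference*
  (experimental/data) sample of each comparison: the bound must be fixed by
  the reference, not by the candidate under test.
- **Gate-then-rank.** Steps 1–2 are pass/fail gates (step 2 passes when the
  simulation's significance pattern matches the data's); step 3 ranks by
  ascending AICc. Failed candidates rank below all passers; `gate=False`
  gives pure-AICc ranking. Both the sim and data step-2 verdicts are
  recorded in `SelectionResult` regardless.
- **AICc.** Natural log (the standard AIC convention); k counts every
  non-intercept coefficient including interactions; N is the number of
  cells in the data. Intercept-only models (k = 0) are valid baselines.
- Per-individual SSEs pair sim and data individuals in sorted order and
  sum; neighbour bins are {1, 2, 3+}.

## The synthetic generator: what it does and does not emulate

Defaults (one set for all individuals; between-plant variation is not
emulated): mother sizes gamma(8, 12.5) µm² (mean 100, sd ≈ 35), SPCH
intensities N(100, 25) a.u., mother neighbours Poisson(0.8) (so SLGCs span
the 1/2/3+ bins with sensible mass), asymmetry beta(5, 12) (mean ≈ 0.29,
negligible mass above 0.5), |λ| exponential with class means 0.26 (1
neighbour) and 0.55 (2+) per hour — implying mean declines of 23% and 42%
per hour, the realistic range for SPCH loss after birth — bleaching
1.8 %/h, sampling every 40 min for 480 min, multiplicative log-normal
measurement noise with CV 0.10 (mean-corrected, so per-timepoint
expectations equal the noiseless curve), and fate coefficients
(intercept 0.4; size −0.02 /µm²; [SPCH]dip +1.0 per a.u./µm²; neighbours
−0.5), which put the overall division proportion near one half with a
monotone decline across neighbour bins. ln(cell area) for standalone
allometry samples is uniform on [2.5, 5.5] (≈ 12–245 µm²), spanning small
SLGCs through large (>150 µm²) cells.

Not emulated: tissue geometry and neighbour rewiring (positions, perimeters,
total-neighbour counts and contact fractions in the cell table are
decorative draws), nuclear growth within a trajectory (nuclear area is held
at its birth value), the post-dip SPCH rise of dividing cells (trajectories
are pure decay, so dip *detection* on cohort trajectories finds the window
edge; dedicated U-shaped fixtures test the dip locator), multi-generation
lineages, and meristemoid fate. Passing tests on this generator therefore
demonstrate correctness of the estimators and the internal consistency of
the simulator–selector loop under the stated distributional assumptions,
not performance on real imaging data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which sampling error is well inside each tolerance: allometry
refits at n = 500 (20 seeds) and n = 2000 for the residual scale;
simulations at 4 × 1000 cells (the model's native population size);
synthetic "experimental" cohorts at 4 × 65 cells, matching the scale of a
typical tracked dataset (~260 cells); TOST calibration at 2000 replicates
of n = 50. Random draws all flow from `numpy.random.Generator` seeded via
`SeedSequence` spawning, so any fixed seed reproduces every output
byte-for-byte. Tolerances for stochastic recoveries are stated in standard
errors where a closed form exists (3 SE), otherwise as conservative
relative bounds (10–15% for likelihood-based shape parameters at n ≈ 4000).

## Known limitations

- The asymmetry-noise interpretation and the TOST-bound source are
  genuinely under-determined by the procedure being modelled; both are
  configurable and the defaults are documented above.
- Exponential decay-magnitude fits condition on decline (λ < 0); under
  heavy trajectory noise this selection slightly inflates the fitted means
  for slowly declining classes.
- The CART held-out alpha selection is a point estimate from one split;
  on label-noise data the selected subtree is rarely the root leaf itself
  (any overfitted subtree can beat the majority baseline on a finite test
  split), though pruning always removes part of the full tree.
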