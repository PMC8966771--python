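# Methods

This note records the modelling choices, defaults and numerical decisions
behind `canopygp`, and what the synthetic experiments do and do not
establish about real field data.

## Canopy model and thermal time

Canopy development is expressed on a growing-degree-day (GDD) clock: the
cumulative daily mean temperature above a base of 8 °C (the usual soybean
base), summed from the sowing date, with no sub-daily interpolation.
Observation dates are mapped to thermal time by indexing the daily
cumulative series (sowing day = index 0).

LAI follows a logistic-growth-minus-exponential-senescence curve with five
parameters: `LAI_amp` (dimensionless, canopy maximum), `r_g` and `r_s`
(per degree-day), `T_g` and `T_s` (degree-days).  The curve is negative past
the senescence zero-crossing `T_s`; since a pixel fraction cannot be
negative, LAI is clamped at zero before the Beer–Lambert conversion
`GF = 1 − exp(−k·LAI)` with extinction coefficient `k = 0.5`.  The logistic
is evaluated through `scipy.special.expit` and senescence exponents are
clipped at 700 so the curve is finite for any degree-day input.  The
GF↔LAI pair inverts to 1e−10 absolute for `k·LAI` up to ≈ 20; closer to
full cover the inversion is limited by float64 resolution of `1 − GF`.

## Two-stage curve fitting

Drought plots are too noisy to fit alone, so estimation is staged:

1. **Genotype-level joint fit.** All plots of a genotype within one year
   (both watering treatments) share `r_g, r_s, T_g, T_s`; `LAI_amp` is free
   per plot, the finest level consistent with treating only the amplitude
   as treatment-dependent.  `(T_g, T_s)` are searched on a 7×7 inclusive
   lattice over (300, 1200) × (1400, 3000) degree-days (spacing 150 and
   266.7); at each cell Nelder–Mead minimises the weighted cost over the
   logs of the remaining parameters (log-parameterisation enforces
   positivity without constraints).
2. **Per-plot refinement.** The lattice narrows to ±200 (`T_g`) / ±400
   (`T_s`) around the stage-1 optimum, same 7-point resolution, truncated
   at the global ranges; the simplex starts from the stage-1 values.  The
   stage-1 point is always kept on the refinement lattice (truncation would
   otherwise drop it), and if refinement somehow ends above the plain
   stage-1 curve on that plot, the stage-1 parameters are returned — so the
   per-plot cost never increases across stages.

The cost is Σ_d Σ_i (y_id − ŷ_id)²/ȳ_d, where ȳ_d is the mean observed GF
of the plot's environment on date d, computed once before fitting;
measurement noise of GF grows roughly in proportion to its mean, and the
weighting equalises the dates.  Dates with ȳ_d < 1e−4 are excluded — they
carry no canopy signal and would otherwise blow up the weights.

**Initialisation.**  The weighted cost has a strong degenerate attractor
(very large amplitude with a very slow growth rate mimics the early
exponential rise), and a simplex started from fixed defaults regularly
falls into it.  Every lattice cell therefore screens a small deterministic
candidate grid of starts — `r_g ∈ {0.005, 0.01, 0.02, 0.04}`,
`r_s ∈ {0.001, 0.004, 0.012}`, amplitudes matched so each plot's implied
LAI maximum equals the value observed — and the simplex starts from the
cheapest candidate.  Fits are fully deterministic.

Simplex settings: `fatol 1e−9`, `xatol 1e−6`, 2000 iterations per cell.
Ties across lattice cells break toward the lowest `(T_g, T_s)`.

**What recovery means here.**  Because the timing parameters live on a
lattice, rate and amplitude estimates compensate any off-lattice timing
truth; sub-percent recovery of `r_g`/`r_s` is only meaningful (and is
verified) for truths whose `(T_g, T_s)` the lattice can represent.  For
arbitrary truths the guarantees are: timing within the final grid spacing,
and amplitude — the parameter breeding cares most about — with a median
error under 10% at 5% mean-proportional noise and 20 flights.

## Genotypic values and G-BLUP

Plot phenotypes (per-date GF, per-plot curve parameters) decompose as
`y = μ1 + Lβ + Ws + e` with block effects β fixed (few levels; coded
sum-to-zero so μ is the general mean) and genotype effects
`s ~ N(0, σ_s² I)` random; genotypic values are `g = μ + BLUP(s)`.  GF
genotypic values are estimated separately per flight date × environment.
Without replication σ_s² is unidentifiable and plot means are returned,
flagged.

The genomic relationship matrix is `G = XXᵀ/c` on centred, unit-variance
marker codes with `c = trace(XXᵀ)/n`, making the mean diagonal one and
putting h² on the standard scale (VanRaden-equivalent up to scaling; the
markers' own QC: MAF ≥ 0.025, missing rate < 0.05, greedy LD pruning with
window 50 / step 5 / r² ≥ 0.95 removing the later marker, mean imputation).

All one-random-effect REML fits use the spectral trick: rotating into the
kernel's eigenbasis reduces the restricted likelihood to a smooth scalar
function of λ = σ_e²/σ_u², profiled on a log grid over [1e−5, 1e5] by
bounded scalar minimisation — exact, with no convergence failures by
construction.  Test-genotype predictions are the conditional mean
`G_te,tr (G_tr + λI)⁻¹ (g_tr − m̂)`; their REML plug-in conditional
variances feed the predictive draws used by TGPG.

## Multi-trait model

The J-variate model stacks genotypic values with genetic covariance
`K ⊗ G` and residual covariance `R ⊗ I`, fitted by Gibbs sampling with
conjugate updates throughout (genetic effects batched over the
eigencomponents of G; inverse-Wishart updates for K and R; Gaussian means;
data augmentation of missing cells, grouped by missingness pattern).
Priors are weakly informative inverse-Wisharts with J+2 degrees of freedom
and 0.5·I scale *on internally standardised variates* — the sampler
standardises every variate to unit variance and rescales all outputs,
because raw parameter scales (an amplitude ~3 vs a rate ~0.004 vs a timing
~2000) differ by ten orders of magnitude and destroy the conditioning of
the covariance updates.  Chain defaults are 15,000 iterations, 5,000
burn-in, thinning 5 (2,000 retained draws); the experiments below use
shorter chains, stated where used.  Retained draws are exactly
`(iterations − burn_in)/thin`; a fixed seed reproduces the chain bit for
bit.

Supporting variates for the multi-trait models are ranked by
`s(h²) + s(|r|)` — both standardised over the candidate set — with h² from
the training-set G-BLUP of each candidate and r the correlation with the
target over training genotypes; ties break on higher h², then label.  The
candidate set never contains variates of a held-out environment.  Models
use 1 target + 10 supports (7 + the three latest early flights under CV3).

**TMGP composition.**  The two-step multi-trait model fits the five curve
parameters of the target environment jointly (J = 5); under CV2/CV3 the
same five parameters from the other environments join as supports, which
is exactly where the test genotypes' own records can inform the held-out
environment.  Under CV1 the test genotypes are unobserved everywhere, so
other-environment supports are omitted.

## Growth-conditioned prediction (ABC)

TGPG/TMGPG turn parameter uncertainty into trajectory clouds: TMGPG uses
the raw MCMC draws; TGPG — whose first stage is REML-based and has no
draws — samples each parameter independently from the asymptotic
predictive normal around its BLUP.  For each test genotype, every draw is
converted to a GF trajectory, the Euclidean distance to the observed
early-season GF (on the GF scale) is computed, the `n_keep` closest draws
are retained (default 60 of 60,000; the experiments here use 6 of 6,000),
and the prediction is the mean of the kept trajectories over all dates.
Draws with non-positive rates receive infinite distance rather than being
dropped, preserving the draw count; with no early observations at all the
selection degrades to the plain mean over draws.

## Cross-validation

Genotype folds are balanced random partitions (sizes differ by ≤ 1),
seeded per repeat (`seed + repeat`), identical across schemes so that the
per-date GP/TGP predictions coincide between CV1 and CV2 by construction.
CV2 masks only the test genotypes' data in the held-out environment; CV3
additionally keeps their early-season GF (the growth cycle splits into
equal halves, the extra flight of an odd count going to the early period)
and scores late dates only.  Every runner audits its masked panel — an
assertion fails if any held-out value survives into training.  Accuracy is
the Pearson correlation between genotypic values and predictions per
environment × date over test genotypes; model contrasts are ratio
improvements (mean_A/mean_B − 1)·100%.

## Synthetic data

The simulator emulates a germplasm trial: 200 genotypes by default, 3
years × two watering treatments, 2 blocks, 16 flights evenly spaced days
14–75 after sowing, sowing on 1 July, temperatures ≈ 22–28 °C giving
roughly 17 degree-days per day.

* **Markers** (2,000 by default) come in LD blocks of 10 noisy duplicates
  of a latent variant (5% deviation rate) with U-shaped Beta(0.4, 0.4)
  allele frequencies.  The block structure is deliberate: a panel of this
  size with fully independent markers caps G-BLUP accuracy near
  √(n/(n+m)) ≈ 0.4 even for fully heritable traits, whereas real germplasm
  panels owe their predictability to local LD.
* **Parameters** per genotype × environment are
  `mean_env · (1 + a + w)`, with marker-determined deviations `a`
  following a unit-diagonal 5×5 genetic correlation matrix (moderate
  positive defaults) and variance `h²·cv²`, and iid non-genetic deviations
  `w` with variance `(1−h²)·cv²` (`cv = 0.12`); default heritabilities
  0.8/0.6/0.3/0.7/0.3 for amplitude, growth rate, senescence rate, growth
  timing, senescence timing — high for growth traits, low for senescence
  traits, which short flight campaigns barely observe.
* **Drought** multiplies the amplitude by 0.55 and the growth rate/timing
  mildly (0.9/0.98).  Within this curve family a strong timing shrink
  would make drought canopies overtake controls mid-season; keeping the
  drought curve below the control throughout the season (where the canopy
  is established) was prioritised over reproducing a large timing shift.
* **Observations** add plot-level lognormal parameter jitter (σ = 0.02,
  which separates genotypic from residual variance in the mixed model) and
  Gaussian GF noise with standard deviation ν·(mean GF of the date)
  (ν = 0.05), clipped to [0, 1) — the same mean-proportional noise
  assumption that motivates the weighted fitting cost.

Everything is deterministic given the config seed; regenerating reproduces
identical tables.

**What the simulator does not capture:** genotype × environment
interaction of genetic effects (environments shift means only), spatial
field trends, temporal autocorrelation of measurement error, segmentation
artefacts of real imagery, population structure beyond LD blocks, and
senescence behaviour beyond the five-parameter family.  Passing tests
demonstrate the statistical machinery under its own assumptions, not
image-pipeline robustness.

## Experiment scales

The verification experiments are sized for a single CPU: noise-free
recovery uses 3 genotypes × 2 environments × 2 blocks with 20 flights to
day 150 (so senescence is identified); noisy recovery 13 genotypes
(52 plots) × 3 seeds; heritability calibration 20 replicates at n = 200;
the single-trait-limit chain 3,000 iterations at n = 100; genetic
correlation recovery three 4,000-iteration chains at n = 200; and the CV3
experiment five replicates of 200 genotypes × one year with one evaluation
fold, 8,000-iteration chains (6,000 retained draws) and ABC keeping 6.
With one evaluation fold per replicate, genotypes are not each tested once
per repeat — the full-fold invariant is exercised separately with cheap
models.

## Known limitations

* The fitting lattice quantises `T_g`/`T_s`; rate estimates absorb the
  quantisation error for off-lattice truths (see above).
* TGPG's predictive draws ignore parameter cross-covariances (independent
  normals per parameter); TMGPG's MCMC draws carry them.
* REML and the Gibbs sampler treat the genotypic values as observed,
  ignoring their estimation error from the plot stage.
* Block effects are treated as fixed; with two balanced blocks the choice
  is inconsequential, with many incomplete blocks a random-effect
  treatment would be preferable.
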