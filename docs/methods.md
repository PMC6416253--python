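# Methods

## Data model and preprocessing

An `ExpressionPanel` holds monthly relative expression keyed by
(gene, individual, year, month). Two preprocessing steps define the
analysis-ready form:

- **Normalization.** Each (gene, individual) series is z-scored to mean 0,
  sd 1 using its own sample statistics (ddof = 1). Statistics are computed
  from the values present at call time, so the default pipeline order —
  normalize, then mask — normalizes from growing-season (June–October)
  observations only. The alternative order (mask first, so winter zeros
  enter the statistics) is available simply by calling the two functions
  the other way around; we default to normalize-then-mask because the
  winter zeros are an analysis convention, not measurements. Constant
  series are an error: they cannot reach unit variance.
- **Winter masking.** Deciduous trees carry no leaves from November to
  May; those months are set to exactly zero and missing winter months are
  created as zero records, so every individual contributes complete
  12-month calendar years (24 points for 2 years, 36 for 3). Missing
  *growing-season* observations are never imputed — they raise an error.

## Delay embedding and pooling

Embeddings use lag tau = 1 month (the sampling interval; no evidence
supports longer lags at this resolution) and strict segment bookkeeping:
no lag vector ever spans two individuals. Winter zeros are treated as
ordinary values inside embedding vectors — they were *set*, so they are
part of the analyzed series; an `exclusion_matrix` keeps a Theiler window
of ±1 time step within segments so temporally adjacent vectors cannot act
as neighbors, while cross-individual neighbors are always temporally
eligible.

Because 24–36 points per tree cannot support state-space reconstruction
alone, individuals are pooled dew-drop style: per-individual series (each
independently z-scored, which is the scale-matching premise of the
technique) are embedded separately and the vectors concatenated into one
composite library. Neighbors for a target in one tree may come from any
tree. At these panel sizes the pooled library outperforms the *average*
single individual but not always the best-of-n single individual — the
best-of-n comparison is upward-biased by overfit 22-vector libraries, so
"pooled ≥ best single" should not be expected at 24-point scale.

## Forecasting instruments

- **Simplex projection** (nearest-neighbor forecasting): each target's
  prediction is the weight-normalized average of the futures of its E+1
  nearest neighbors, weights `exp(-d_i/d_1)`; when the nearest distance is
  zero, weights are uniform over the exact matches. Targets with fewer
  than E+1 eligible neighbors are skipped and counted.
- **Embedding-dimension selection:** E* maximizes leave-one-out simplex
  skill over E = 1..5 by default; rhos within 1e-6 of the maximum count as
  ties and the smallest such E wins (on noise-free deterministic series
  every E reaches rho ≈ 1 up to float dust, and the smallest sufficient
  dimension is the meaningful answer).
- **S-map** (locally weighted linear forecasting): weighting
  `exp(-theta * d / d_mean)`; the local solve is ridge-regularized
  (lambda = 1e-8 scaled by the squared design magnitude) and never hard
  fails on singular designs. The nonlinearity statistic is
  delta_rho = max_theta rho(theta) − rho(0) over a 12-point theta grid
  (0–8); its null distribution comes from per-segment phase-randomized
  surrogates (linear dynamics, same spectrum), p < 0.05 flags
  state-dependence. No published description of the original significance
  machinery for this step exists, so the surrogate Δρ convention of the
  EDM literature is used and stated here as a design choice.

## Cross mapping and the causality decision

Direction convention: to test cause X → effect Y, the *effect* Y is
embedded (its history carries the drivers' signature) and Y's neighbors
estimate contemporaneous X (prediction lag tp = 0, the original CCM
formulation). E is the optimal embedding dimension of the library (effect)
variable. Bootstrap libraries are drawn **with replacement** (duplicated
vectors occupy neighbor slots independently); a without-replacement mode
exists for sensitivity checks. ρ_min is sampled at library size E+1, ρ_max
at the full pooled library, 1,000 replicates each by default. Degenerate
correlations (constant predictions) are defined as 0.

Seasonal surrogates decompose each individual's series into a
calendar-month mean profile plus residual, phase-randomize the residual
(Ebisuzaki: amplitudes kept, phases uniform, conjugate-symmetric), recombine,
and re-impose winter zeros. Two exact-preservation properties follow from
one observation: the monthly profile is the orthogonal projection onto the
DFT annual harmonics (frequencies that are multiples of the number of
years), whose residual coefficients are zero and remain zero under phase
randomization. Hence every surrogate reproduces the original per-month
means and the residual amplitude spectrum to machine precision — no
re-centering step is needed. Each surrogate is scored with a single
deterministic full-library pass (configurable to a bootstrap mean); the
full-library neighbor weights are computed once and reused, which makes
1,000 surrogates nearly free.

The decision per ordered pair:

- criterion 1: mean ρ_max > 0 and mean ρ_max > 95th percentile of ρ_min;
- criterion 2: mean ρ_max − 95th percentile of ρ_surr > ε,

with ε = 0.02 at ≤ 24 points per individual, 0.01 at ≥ 36, linearly
interpolated between (the tightening reflects the higher type-one-error
risk of shorter series). "95% upper confidence limit" is implemented as
the one-sided 95th sample percentile (97.5th available by configuration).
Networks run all n(n−1) ordered pairs with **no multiplicity correction**
by default, faithful to the screening character of the procedure; a Holm
option on the empirical surrogate p-values can only remove edges.

## Synthetic data: what it emulates and what it does not

The generator produces coupled logistic maps — the canonical cross-mapping
benchmark, chosen because unidirectional causality is provable by
construction — iterated once per growing-season month (June–October), with
no latent update over winter (dormancy). Observations multiply the latent
state by a seasonal factor `1 + A·cos(2π(m−7)/12)` peaking in July and add
Gaussian noise; panels are then normalized and masked exactly like real
data. Each individual starts from independent initial conditions after a
200-step burn-in; one RNG stream per panel is split per individual by a
fixed key, so identical spec + seed reproduces bit-identical panels.

Default study conditions: coupling 0.32, observation noise sd 0.05,
seasonal amplitude 0.3, and growth rates 3.7 (driven gene) / 3.6 (driver).
The rates were chosen once under three constraints and are not tuned per
experiment:

1. **Chaotic band** (≈ 3.6–4.0), excluding periodic windows.
2. **No synchronization.** At coupling 0.32 many rate pairs let the driven
   map become a function of the driver's state (auxiliary-system test:
   duplicate driven copies converge). Under synchronization the reverse
   direction is *genuinely* predictable and no statistical criterion can
   reject it, so synchronized regimes are invalid as a benchmark with
   "provable unidirectional causality".
3. **Single-band driven dynamics.** Logistic rates in ≈ 3.57–3.68 produce
   two-band chaos whose high–low alternation is deterministic; after
   burn-in, nominally independent individuals share the same band phase,
   a hidden common clock that creates real mutual predictability between
   uncoupled genes and inflates false positives under the null. The driven
   gene therefore sits at 3.7 (single band); the driver sits at 3.6, whose
   strong band structure makes it self-predictable enough for
   contemporaneous cross-mapping — under the null (coupling 0) only one
   series carries the clock, so no shared structure arises, which the
   type-I measurements confirm.

Measured operating characteristics at the default study conditions
(3 individuals × 24 masked points, n_boot = n_surr = 1,000, 20 seeds):
true-direction power ≈ 0.35, reverse-direction calls ≈ 0.10, false
positives under the coupling-0 seasonal null and the fully independent
null both 0.00. The limited power is intrinsic, not an implementation
artifact: propagating the observation noise through the cross-map
inversion gives a recovery error of order σ/(c·x) ≈ 0.3 against a driver
sd of ≈ 0.25, capping full-library skill near ρ ≈ 0.5 at these panel
sizes; at 6 individuals × 36 points the same test reaches ≈ 0.9 power.
Reverse-direction skill at coupling 0.32 is genuine driven-variance (it
*increases* with series length), which is why power and reverse-error
trade off against each other through the coupling itself.

The skill response to coupling is monotone over 0–0.25
(0.00 → 0.79 → 0.85) and then drops sharply (≈ 0.20 at 0.3): the summed
forcing shifts the driven map's effective growth rate across a regime
boundary. Monotonicity holds within a regime, not globally.

The 7-gene motif (FE → {NPF1..4} → FT, FE → FT, FE → FTIP1; 10 true edges)
uses coupling 0.32 on the FE fan-out and 0.12 on FT's five-parent fan-in —
the summed forcing on FT must stay small enough to keep its state in
[0, 1], which bounds per-edge detectability. Measured recovery at
6 × 36 points (n_boot = n_surr = 200, 10 seeds): median precision ≈ 0.35,
median recall ≈ 0.45. The main error sources are common-driver confounding
(genes sharing FE as ancestor cross-map each other) and the genuine
reverse-direction skill discussed above — both known limitations of
pairwise cross-mapping, not of this implementation.

What the generator does **not** emulate: probe-level microarray noise,
slow year-scale masting memory (a resource-budget carbohydrate model is a
possible extension, not core), gene-specific seasonal phase, or trends.
Passing tests therefore demonstrate correctness of the machinery and its
operating characteristics on benchmark dynamics — not field performance on
real transcriptomes, whose smoother, more strongly seasonal trajectories
are in several respects *easier* for this procedure.

## DEG screen

A year counts as a floral induction year for a tree when the following
spring's proportion of reproductive buds exceeds 0.4 (strictly); induction
precedes anthesis by one year, and years without a following-spring
observation stay unlabeled. Each gene is screened by a two-factor
fixed-effects ANOVA — induction status and season (summer = Jun–Aug,
fall = Sep–Oct) — with tree identity as a fixed blocking factor
(`value ~ induction + season + tree`, type-II F-tests via statsmodels),
no interaction term by default, and no correction across genes (the screen
keeps raw p < 0.01). A strata-permutation alternative (induction labels
permuted within tree, season labels globally) is provided for robustness;
note that with 3 trees × 2 years it has only 8 distinct permutations and
cannot resolve small p-values. Measured calibration: type-I error 0.013 at
alpha 0.01 over 1,000 null genes; power 0.99 for a 2-sd induction shift.

## Numerical and reproducibility choices

- Pearson ρ of a constant vector is defined as 0 (affects only degenerate
  libraries).
- Exact distance ties at d₁ = 0 use uniform weights over the zero-distance
  neighbors.
- All stochastic stages (bootstrap, surrogates, simulation) take seed
  keys derived from one base seed by fixed integer suffixes; a fixed-seed
  re-run of the full pipeline reproduces verdict tables byte-for-byte.
- Analysis scale: tests and the acceptance script use n_boot = n_surr =
  200 for the 42-pair motif sweep and 200–1,000 elsewhere; the package
  default remains 1,000/1,000.

## Known limitations

- Power at 24-point panels is modest (see above); negative verdicts on
  single pairs are weak evidence of absence.
- Strong unidirectional coupling produces genuine reverse-direction
  predictability; the two criteria reduce but cannot eliminate those
  calls.
- Common-driver confounding is not addressed by pairwise CCM; motif
  precision reflects it.
- Time-lagged cross-map scans, multivariate embeddings, and
  mixed-effects pooling are out of scope.
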