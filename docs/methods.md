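# Methods

## The model

Environmental DNA (eDNA) surveys of cryptic aquatic species observe
detection, not presence. The design modelled here is three-level: sites
(tree islands, paired colony/control), ~9 one-litre water samples per site,
and five droplet-digital-PCR (ddPCR) replicates per sample. The hierarchy is

    z_i   ~ Bernoulli(ψ_i),              logit ψ_i   = x_i'β
    a_ij  | z_i = 1  ~ Bernoulli(θ_ij),  logit θ_ij = w_ij'α
    y_ijk | a_ij = 1 ~ Bernoulli(p_ijk), logit p_ijk = v_ijk'δ

with `a_ij = 0` forced when `z_i = 0` and `y_ijk = 0` when `a_ij = 0`.
ψ is site occupancy (the island holds target eDNA), θ sample occurrence
(spatial patchiness of eDNA within the island's water body), p replicate
detection (PCR-level sensitivity). Because inhibitor-removal treatments can
destroy target molecules, ψ and θ are interpreted as *minimum* rates.

Island type enters ψ with cell-means coding — one coefficient per type, no
global intercept — so each type's occupancy is `logit⁻¹` of its own
coefficient and the two posteriors can be compared directly. All numeric
covariates (collection date at the sample level; time of day and water
depth at the replicate level) are centred and scaled with the SD over the
units at their own level (denominator n−1). Scaling metadata is stored on
the dataset so curves can be mapped back to natural units.

Derived quantities per posterior draw: ψ per island type at the type's
design row (numeric covariates at their means), θ̄ as the mean of
`logit⁻¹(w'α)` over all observed samples, p̄ as the mean of
`logit⁻¹(v'δ)` over all observed replicates. Averaging over observed units
(rather than evaluating at covariate means) was a genuinely open choice;
observed-unit averaging was picked because it is the quantity a repeat of
the same survey would experience.

## Sampling

The sampler is a Gibbs scheme. Latent states have closed-form full
conditionals: with `q_ij = Π_k (1 − p_ijk)` and `r_i = Π_j (1 − θ_ij)`,

    P(a_ij = 1 | z_i = 1, y_ij· = 0) = θ_ij q_ij / (θ_ij q_ij + 1 − θ_ij)
    P(z_i  = 1 | a_i·  = 0)          = ψ_i r_i  / (ψ_i r_i  + 1 − ψ_i)

and both indicators are 1 with certainty when anything below them was
detected. Coefficient blocks are updated conjugately by Pólya-Gamma
augmentation: ω ~ PG(1, x'coef) per unit turns each Bernoulli-logit block
into a Gaussian linear problem under the independent Normal(0, prior_sd²)
prior. β regresses z on all sites, α regresses a on samples within occupied
sites, δ regresses y on replicates within occurring samples; when a block
has no units in a given sweep it draws from its prior (verified against the
prior's moments in the tests). Update order is fixed — a, z, δ, α, β — for
reproducibility; a master seed drives both the numpy stream and the
Pólya-Gamma stream, so equal seeds give identical chains.

The PG(1, c) sampler is this package's own implementation of Devroye's
exact rejection algorithm (truncated inverse-Gaussian body + exponential
tail, alternating-series squeeze), numba-jitted, and is validated against
the distribution's closed-form mean `tanh(c/2)/(2c)` and variance
`(sinh c − c) sech²(c/2)/(4c³)`. An adaptive random-walk Metropolis
fallback (Robbins–Monro step adaptation, target acceptance 0.44) is
selectable via `sampler="rwm"`; it mixes more slowly and exists for
cross-checking the augmented sampler.

Defaults: 100,000 iterations, burn-in 5,000, no thinning, `prior_sd = 2.0`
(weakly informative: keeps `logit⁻¹` of a prior draw near-uniform on (0,1)).
Linear predictors are clipped at ±35 before the logistic transform; at
double precision `logit⁻¹(±35)` is within 7e−16 of {0, 1}, so the clip is
numerically inert and only guards `exp` overflow. Initialisation: z and a
start at the observed detection pattern, coefficients at 0. Posterior
summaries are medians with equal-tailed 95% credible intervals; percentiles
use linear interpolation between order statistics.

## WAIC

Model comparison uses WAIC computed from the *site-level marginal
likelihood* — latents integrated out analytically — because WAIC needs a
well-defined predictive density per exchangeable unit, and sites are that
unit here. Per site and draw,

    L_i = ψ_i Π_j B_ij + (1 − ψ_i) 1{y_i·· ≡ 0},
    B_ij = θ_ij Π_k p^y (1−p)^{1−y} + (1 − θ_ij) 1{y_ij· ≡ 0}.

`lppd_i = log(mean_draws L_i)` and `penalty_i = var_draws(log L_i)` (the
variance-based pWAIC). Reported as `lack_of_fit = −2 Σ lppd_i`,
`predictive_variance = 2 Σ penalty_i`, and their sum; the decomposition is
exact by construction and asserted on every output. Likelihood products use
log-space accumulation; the mean over draws is floored at 1e−300 before the
log, and a site whose likelihood underflows in *every* draw raises an error
naming the site. Ranking is a stable ascending sort, so tied models keep
input order.

## Droplet quantification

A ddPCR reaction partitions ~15,000–20,000 droplets of nominal volume
v = 0.00085 μL (the platform value; configurable — the analysis chain never
depends on it beyond units). Under Poisson partitioning the MLE from m1
positives of m droplets is `λ̂ = −ln(1 − m1/m)/v`, with delta-method SE
`√(m1/(m(m−m1)))/v`. The 95% CI is Wald on log λ̂, back-transformed
(`λ̂ e^{∓1.96 se/λ̂}`), which respects positivity; a plain Wald interval is
available by option. Replicate wells of one run are pooled by summing
droplet counts before estimation. When a sample was re-run after additional
inhibitor-removal rounds, the run with the highest pooled concentration is
selected (extra treatment can only lose target), ties to the latest run.

The limit of blank (LOB) is the maximum pooled concentration over all
negative controls (field, filtration, extraction, no-template); samples *at
or below* it are zeroed along with their replicate detections. The LOB is
applied at the sample level — within a retained sample a replicate scores
detected iff its well has ≥ 1 positive droplet — because the blank
contamination evidence is a sample-level quantity; a replicate-level screen
is available via `level="replicate"`. PCR inhibition, scored as
`1 − IPC_sample/IPC_standard` clamped to [0,1], is reported as QC metadata
and never gates detections (target assays remain readable in inhibited
wells).

## Field statistics

Missing water temperatures (thermometer failures) are filled by OLS of
temperature on collection time over the measured samples; imputed flags are
carried through every downstream table and imputed rows are excluded from
the time–temperature Pearson correlation by default. The published
imputation procedure is not recoverable, so this regression is an
approximation and is flagged as such. Colony/control pairs are dropped from
the concentration comparison when the median control temperature is at
least 8 °C above the colony median (warmer water degrades eDNA faster,
biasing the comparison); the boundary case is excluded. A site's "total
concentration" is the *sum* of its post-LOB sample concentrations — the
only reading consistent with site-level summaries that exceed the largest
single sample. The paired t-test uses colony − control differences, so a
positive mean means more eDNA at colonies; |t| is what should be compared
across sign conventions. Percentages are rounded half-to-even to one
decimal. "Before 11AM" means strictly before 660 minutes.

## Synthetic data

`generate_dataset` simulates the full chain with known truth. Covariate
emulation is deliberately minimal: collection times uniform on 08:00–13:00,
temperature = 11 + 0.02·minutes + N(0, 3) °C (a positive daily gradient in
a plausible 19–35 °C range), one depth per site uniform on 10–100 cm, one
collection date per pair on consecutive April days. Latents follow the
logit-linear truth on covariates standardized within the generated dataset,
exactly as the model will see them.

Droplet counts are the only source of detections: in an occurring sample,
the per-droplet probability is attenuated so that
P(≥1 positive droplet) = `logit⁻¹(v'δ)` *exactly*
(π = 1 − (1 − p)^(1/m)), keeping the quantification chain exercised
end-to-end while making replicate positivity match the detection logits.
The nominal concentration λ ~ LogNormal is carried as truth metadata. An
optional false-amplification channel gives eDNA-free replicates a spurious
burst (1 + Poisson(1) droplets) with a small per-replicate probability, to
exercise the LOB screen; it is off by default. The default seed is
20190410.

What the generator does **not** emulate: spatial correlation between
sites, inhibition-dependent detection loss, concentration-dependent
detection (detection depends on covariates only), or realistic
concentration–droplet coupling in the attenuated regime. Passing recovery
tests therefore show the estimator is correct *for this data-generating
law*, not that real surveys meet its assumptions.

`everglades_fixture` is a fully deterministic dataset reproducing the
count-level summaries of the field study this package is modelled on
(sample/site positivity by stratum, concentration extremes and site-total
means, morning-sampling and temperature-window tallies, three
temperature-excluded pairs, a 0.258 copies/μL NTC as the LOB source).
Droplet counts are chosen by inverting the Poisson-partition estimator,
tuning the pooled droplet total within 5 wells × 15,000–20,000 droplets so
each target concentration is reproduced to 4 significant figures. Filler
concentrations (0.5559 and 0.333/0.334 copies/μL) are constrained only by
the published sums and extremes and are otherwise arbitrary. The fixture
makes no attempt to match model-based estimates (ψ, θ̄, p̄) or printed
standard deviations — those require the raw field data, which were never
deposited.

## Problem sizes used in validation

Simulation studies run at 150 sites (75 pairs), 6 samples per site, 5
replicates: parameter recovery uses 20 datasets × 15,000 iterations
(burn-in 1,000); the WAIC preference study uses 20 datasets × 2 models ×
3,000 iterations (burn-in 500, 2,500 retained draws). These sizes give
stable Monte-Carlo behaviour — coverage counts within one or two of
nominal, win rates far from the decision boundary — while keeping a full
validation run to a few minutes.

## Known limitations

- Single-chain sampler; convergence is assessed by ACF/MCSE diagnostics,
  not cross-chain R̂.
- No spatial autocorrelation, multi-season dynamics, or abundance
  (N-mixture) extensions; concentration values never inform the detection
  model.
- The LOB is a global threshold; plate-specific alternatives are out of
  scope.
- The RWM fallback is tuned for small coefficient blocks (≤ 3) and should
  not be used with rich covariate sets without checking acceptance rates.
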