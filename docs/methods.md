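# Methods

`dendrocp` implements a chain of inferences linking tree radial growth, soil
inorganic-nitrogen supply, atmospheric CO₂, and the decay-gene repertoire of
ectomycorrhizal (ECM) root communities, together with a synthetic-study
generator that produces data from the same models under known ground truth.
This note records the models, the defaults and why they are what they are,
the numerical choices, and the limits of what the synthetic experiments can
show.

## 1. Deterministic dendrochronology

Ring widths (mm, one averaged radial series per stem) and the diameter at
breast height (DBH, cm) measured at sampling anchor the recursion
DBH_{y−1} = DBH_y − 2·rw_y, giving an end-of-year diameter history; a series
of N rings yields N+1 diameters, the first being the diameter before the
first ring formed. Basal area increment is the first difference of
BA = π(DBH/2)²; N rings therefore yield N BAI years and, after the lag
covariate is formed, N−1 analysis rows per tree.

Two conventions worth flagging:

* **The size covariate is predetermined.** The process model uses ln(DBH)
  for the year's growth; using the end-of-year diameter would make the
  covariate contain the response. Both the simulator and the table assembly
  use the diameter *entering* the growth year.
* **The lag covariate is a z-score of log growth.** "Previous-year growth,
  standardized" is ambiguous between raw and log BAI. Standardizing raw
  lognormal BAI has a heavy upper tail (z-scores near 5), and a positive lag
  coefficient then amplifies spikes into a feedback that admits no
  self-consistent series; the z-score of ln(BAI), the scale on which the
  model is linear, is stable and is used throughout. The growth-nitrogen
  efficiency index (below) is standardized on the raw scale, matching its
  explicit definition.

All standardizations use the sample (n−1) SD. Negative BAI (a diameter
decrease) is legal and logged, but the lognormal growth model requires
positive BAI; non-positive years cannot enter the lag either and their rows
are dropped with a warning.

## 2. Growth change-point model

For tree i in year y,

    BAI_iy ~ logNormal(B_iy, σ²_iy)
    B_iy   = (α₁ + J_i α₂) + (α₃ + J_i α₄)·Nminer_i + α₅·ln(DBH_iy)
             + α₆·BAIS_{i,y−1} + α₇·MayTemp_y + SERE_i
    σ²_iy  = a + b·ln(DBH_iy)

with J_i = 1 when the tree's net N mineralization rate exceeds the change
point (uniform prior on (0, 1.25) µg N g⁻¹ d⁻¹, wider than the sampled
gradient). SERE is a zero-mean Gaussian spatial random effect with
covariance σ²_SERE·exp(−φ·d_ij); the exponential-kernel construction is the
standard reading of a spatially explicit random effect with
distance-decaying correlation. Priors: α*, b ~ N(0, 10⁴);
a ~ logNormal(1, 10³); φ ~ U(0.001, 10); 1/σ²_SERE ~ Gamma(10⁻⁴, 10⁻⁴).
The SERE can be tree-level (one coordinate per tree) or site-level (trees
sharing site coordinates collapse to a site effect); both are supported by
passing the corresponding coordinates.

**Sampling.** Given the hyperparameters, the model is jointly Gaussian in
ln BAI: both the SERE field (rank = number of trees) and the coefficient
vector (rank 8) are integrated analytically via nested Woodbury/Cholesky
identities, leaving a 5-dimensional posterior over (ln v_mid, b, cp, φ,
ln σ²_SERE) that an affine-invariant ensemble sampler (differential-
evolution moves, 32 walkers, 2000 post-burn steps by default) explores.
v_mid is the observation variance at the mean ln DBH; sampling that instead
of a removes the near-collinearity of (a, b). The coefficient vector and
the field are reconstructed afterwards from their exact Gaussian
conditionals for every retained draw. The change point stays continuous; J
is recomputed from it at each draw, so the likelihood is piecewise constant
between consecutive observed mineralization values. Half the walkers start
spread across the observed gradient so separated likelihood plateaus are
visited; rank-normalized split R-hat over walkers is reported and values
above 1.05 are flagged in the result rather than raised — the variance and
φ dimensions mix slowly and commonly flag at ~1.1–1.3 while the
change-point and slope summaries are stable (they agree with an independent
profile-likelihood scan to well within one posterior SD).

The variance line a + b·ln DBH may go non-positive for b < 0; draws where
the minimum over observed diameters falls below 10⁻⁶ are rejected, which
truncates b's support at run time.

**Model fit.** R² is reported as the squared Pearson correlation between
observed ln BAI and the posterior-mean process B_iy (including the
conditional-mean field); a Gelman-style variance-ratio variant is available
behind a flag. The quantity is not defined by the source analysis anywhere,
so the package picks the simplest reading and names it.

**Vague-prior edge mass.** With N(0, 10⁴) priors, placing the change point
outside the observed gradient deactivates two design columns, and the
corresponding Occam factor (~ln(prior SD/posterior SD) per identified
coefficient) then *favors* the edge unless the break carries decisive
likelihood. At the full study size the break evidence is hundreds of nats
and the effect is invisible; on deliberately small test fixtures a visible
fraction of posterior mass sits beyond the data, which is the honest
posterior for those priors. Robust summaries (medians, within-range
restrictions) are used where small fixtures are examined.

## 3. CO₂-response stages

GNE_iy = BAI_iy / Nminer_i is each tree-year's growth per unit inorganic-N
supply; GNES is its within-tree z-score. Stage 1 regresses GNES on the
yearly atmospheric CO₂ (centered before fitting; slopes are reported per
µmol mol⁻¹) and standardized May minimum temperature, per tree, with a
shared SERE:

    GNES_iy ~ N(β_i + λ_i·CO₂_y + γ_i·MayTemp_y + SERE_i, σ²_i).

Everything is conditionally conjugate, so a blocked Gibbs sampler updates
the per-tree coefficient triples (batched 3×3 solves), the per-tree
variances, the field, and its variance exactly; only φ needs a random-walk
Metropolis step. β_i and SERE_i share the tree-level intercept and are not
separately identified; their sum is, and λ_i — identified by the within-tree
CO₂ trend — is unaffected, which is all stage 2 consumes. φ mixes poorly
and its R-hat is routinely flagged; λ summaries are insensitive to it.
Posterior means λ̄_i and SDs are exported per tree.

Stage 2 is the change-point regression of λ̄_i on the mineralization rate,

    λ̄_i ~ N((θ₁ + J_i θ₂) + (θ₃ + J_i θ₄)·miner_i, σ²_λ).

Stage-1 posterior SDs are *not* propagated by default (the two-stage
summary-statistic design); an optional measurement-error mode adds them per
tree to the stage-2 variance. Given (cp, σ²_λ) the model is Gaussian and
linear in θ, so θ is integrated analytically and the joint posterior of
(cp, ln σ²_λ) is evaluated exactly on a 501 × 161 grid; reported draws are
exact samples from the discretized posterior (with within-cell jitter).
There is no MCMC in stage 2 and no convergence question; fits are
deterministic given the seed.

**Stage-2 coefficient prior.** Implementing the posterior exactly exposed a
Lindley–Bartlett pathology in the literal N(0, 10⁴) slope priors: for
slopes of natural magnitude ~0.05, most of the exact posterior mass sits on
the "no break inside the data" plateau, because the dead design columns
there escape the Occam factor entirely. A Gibbs sampler initialized near
the data mode simply never visits that region and reports the local mode.
Rather than reproduce a result that depends on sampler blindness, the
default prior SD is auto-scaled to 50× the SD of the supplied λ̄ — still
diffuse by more than an order of magnitude on the data scale — which
removes the pathology (edge mass < 1%); the literal fixed prior remains
available via `SlopeCpSpec(theta_sd=100)`.

**Shape comparison.** The change-point model competes against a linear
null, a logarithmic curve c₀ + c₁·ln m, and an exponential decay
c₀ + c₁·e^(−rate·m) (the last two are reconstructions; their exact
parameterizations were not specified by the source analysis). All are
fitted with the same conjugate-grid machinery (the decay rate gets its own
grid) and ranked by DIC = D̄ + p_D. The plug-in deviance is evaluated at
the posterior means of the shape parameter and variance with the
coefficients at their *conditional* posterior mean there; plugging in the
marginal coefficient mean mixes change-point modes incoherently and
produces the textbook negative-p_D pathology (observed: it handed the
change-point model a spurious ~20-unit DIC bonus on linear data).

## 4. Community-aggregated decay traits

Metagenomic gene-family counts are compositional. Each count is expressed
as an additive log-ratio against the geometric mean of the sample's
near-single-copy orthologue counts (a genome-number proxy):
alr_{s,g} = ln((c_{s,g}+p)/geomean_k(s_{s,k}+p)) with pseudocount p = 0.5
on both sides (the source is silent on zeros; 0.5 is the conventional
choice). The geometric mean runs over every orthologue column, zeros
included after the pseudocount. The transform is exactly invariant to
per-sample sequencing depth as p → 0.

Community biomass is folded back in by multiplying each sample's alr values
by its standardized colonized-root-tip count. "Standardized" is read as
division by the across-sample mean (preserves the sign of the alr); an
across-sample z-score mode exists behind a flag and is documented as
sign-unsafe.

Above/below-threshold contrasts use two-group one-way ANOVA per gene family
with Bonferroni correction over the families tested (the pre-specified
total-abundance contrast is not included in the correction), and the same
ANOVA for morpho-trait aggregates (summed relative abundance of
rhizomorph-forming genera and of each exploration type). Identical groups
return F = 0, p = 1 rather than NaN. If trait assignments cover less than
90% of sequence abundance a warning is emitted and results are still
returned. The package reports the n it used and does not attempt to
reproduce the source's exact F statistics, whose degrees of freedom imply
undescribed sample exclusions.

## 5. The synthetic-study generator

The generator emulates the study design: 54 trees in 12 site clusters
(uniform site centers on an 8×8 landscape, trees inside 0.25-radius discs,
Euclidean distances in arbitrary landscape units), site base rates evenly
spaced over the 0.06–1.19 µg N g⁻¹ d⁻¹ mineralization gradient with
per-tree jitter rescaled to span the range exactly; 38 years (1980–2017) of
growth; a strictly increasing linear CO₂ ramp of +70 µmol mol⁻¹ over the
period; May minimum temperature i.i.d. normal (mean 2.5 °C, SD 1.3 °C,
optional trend) — no generative climate model was available to copy, and
only the standardized series enters any model. Initial diameters are
lognormal around 25 cm (an even-aged ~100-year stand); gene-family counts
are negative binomial around per-sample depth × family relative abundance,
with decay-flagged families enriched below the growth threshold, and
near-single-copy counts tracking depth so the alr cancels it by
construction.

**Lag fixed point.** Because the lag covariate is a whole-series z-score,
the simulator iterates: with the Gaussian noise frozen, the series is
re-simulated using the current z-scores as lag covariates until the
z-scores implied by the realized series match the ones used (sup-norm
10⁻¹⁰). The map contracts only while α₆ stays below the within-tree SD of
log growth; defaults keep the ratio near 0.4. On short series an individual
tree can draw a realized SD below α₆ and turn the map oscillatory; the
simulator then switches to damped iteration and accepts near-consistency up
to 0.05 in z (≤ α₆·0.05 ≈ 0.005 on ln BAI, ~40× below the observation
noise), logging the residual; the pathological noise-free limit is run with
α₆ = 0. The returned BAI is re-derived from the integrated diameter path by
the same basal-area differencing the analysis applies, so the telescoping
identity holds bit-exactly downstream.

**Default effect sizes.** The source reports posterior summaries, not
generative parameters, so defaults were chosen once to land in the same
precision class as the published numbers: a continuous break at 0.53 with
ln-BAI slope 0.3 below and 2.1 above, observation variance
0.02 + 0.005·ln DBH and spatial variance 0.0025 give a change-point
posterior SD of a few hundredths and an R² near 0.9 (the published analysis
prints ±0.01 and 0.94); CO₂ slopes declining from 0.05 z-units ppm⁻¹ to
zero at the 0.39 break with σ_λ = 0.005 make the CO₂ trend the dominant
term of a responding tree's standardized index, which is what a clean
per-tree slope pattern requires. Weaker settings were examined in pilot
runs and produce posteriors several times blunter than the published ones —
informative about the method, but not an emulation of the study.

**What passing tests do not show.** The generator draws from the same model
families the estimators assume; recovery on it demonstrates correctness of
the inference chain, not robustness to the ways real ring series deviate
(missing/locally absent rings, crossdating error, non-lognormal growth
shocks, climate autocorrelation, mineralization measurement error, spatial
anisotropy, amplicon/metagenomic compositional artifacts beyond depth).
Real-data conclusions inherit all of those caveats.

## 6. Problem sizes used in the checks

The bundled verification scripts and tests run the growth model at the full
54 × 38 design (one fit, ~1–2 minutes on a single core), replicate-based
properties at 20–24 replicates of the cheap stages (stage-1 Gibbs at
1500–2500 sweeps, exact-grid stage 2), and unit tests on 20–30 trees with
10–12 year series. These sizes were chosen so the entire suite documents
the method at interactive cost while keeping every statistical check at the
study's own n where it matters (change-point recovery, headline contrast,
calibration, DIC selection).
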