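# dendrocp

Bayesian change-point analysis of tree growth along soil nitrogen
gradients, with spatially explicit random effects, a two-stage CO₂
fertilization-response analysis, and compositional standardization of
metagenomic decay-gene counts.

## The problem

In nitrogen-limited forests, trees hosting ectomycorrhizal (ECM) fungi may
tap nitrogen bound in soil organic matter (N-SOM) when the supply of
inorganic N (measured as the net N mineralization rate, µg N g⁻¹ d⁻¹) is
low. If so, three signatures should co-occur along a mineralization
gradient: (i) annual growth — basal area increment, BAI (cm² y⁻¹) — should
rise only weakly with mineralization below some threshold, and strongly
above it; (ii) growth should respond to rising atmospheric CO₂ only where
the extra N can come from somewhere, i.e. below a similar threshold; and
(iii) the ECM communities below the threshold should be enriched in
decay-associated gene families and foraging morphologies. `dendrocp` is a
tested, reusable implementation of that inference chain, for ecologists who
have per-tree ring series, per-tree soil measurements, and gene-count
tables, plus a synthetic-study generator so every stage can be checked
against a known truth.

## Models

Growth (tree i, year y; J_i flips 0→1 at the change point):

    BAI_iy ~ logNormal(B_iy, a + b·ln DBH_iy)
    B_iy = (α₁ + J_i α₂) + (α₃ + J_i α₄)·Nminer_i + α₅·ln DBH_iy
           + α₆·BAIS_{i,y−1} + α₇·MayTemp_y + SERE_i

with SERE a zero-mean Gaussian spatial effect, Cov_ij = σ²·e^(−φ d_ij),
and change point ~ Uniform(0, 1.25). The CO₂ stage works on the
growth-nitrogen-efficiency index GNE = BAI / Nminer, z-scored within tree
(GNES): per-tree regressions GNES ~ β_i + λ_i·CO₂ + γ_i·MayTemp + SERE_i
give each tree's CO₂ slope λ̄_i, which is then itself analyzed with a
change-point regression against mineralization and compared by DIC with
linear, logarithmic and exponential-decay response shapes. Decay-gene
counts are standardized by the additive log-ratio against the geometric
mean of near-single-copy orthologue counts, rescaled by standardized
root-tip counts, and contrasted above/below the growth threshold with
one-way ANOVAs (Bonferroni across families).

The growth model is sampled by marginalizing everything Gaussian
analytically (SERE field and coefficients) and running an ensemble sampler
on the 5 remaining hyperparameters; the per-tree GNES stage is a blocked
conjugate Gibbs sampler; the slope change-point stage is computed exactly
on a grid (no MCMC). See `docs/methods.md` for assumptions, defaults, and
numerical choices.

## Worked example

```python
import dendrocp as dcp

# generate a synthetic study at the published design and recover the break
gradient = dcp.generate_gradient(54, 12, 0.06, 1.19, seed=1)
truth = dcp.GroundTruth(seed=2)          # growth break at 0.53, CO2 break at 0.39
sim = dcp.simulate_bai_series(gradient, None, truth, 38, seed=2)

post = dcp.fit_bai_model(sim.table, gradient, dcp.BaiModelSpec(seed=3))
cp = dcp.changepoint_summary(post)
print(f"growth change point: {cp.cp_mean:.3f} +/- {cp.cp_sd:.3f} ug N/g/d")
print(f"ln-BAI slope below:  {cp.slope_below_mean:.2f}")
print(f"ln-BAI slope above:  {cp.slope_above_mean:.2f}")
print(f"model fit R2:        {dcp.bayes_r2(post):.3f}")

lam = dcp.simulate_lambda_bar(gradient, truth, seed=4)
m = gradient.set_index("tree_id").loc[lam.index, "nminer"]
s2 = dcp.fit_slope_changepoint(lam, m, dcp.SlopeCpSpec(seed=5))
cp2 = dcp.changepoint_summary(s2)
print(f"CO2-effect change point: {cp2.cp_mean:.3f} +/- {cp2.cp_sd:.3f} ug N/g/d")
print(f"lambda slope below excludes zero: {cp2.below_excludes_zero}; "
      f"above excludes zero: {cp2.above_excludes_zero}")
```

prints (about a minute, single core):

```
growth change point: 0.560 +/- 0.044 ug N/g/d
ln-BAI slope below:  0.43
ln-BAI slope above:  2.00
model fit R2:        0.890
CO2-effect change point: 0.427 +/- 0.041 ug N/g/d
lambda slope below excludes zero: True; above excludes zero: False
```

The simulated truth put the growth break at 0.53 and the CO₂-effect break
at 0.39; both fitted intervals cover their truths, the below/above slope
contrast is credibly nonzero (the growth response to inorganic N is weak
below the break and strong above it), and only the below-break trees show a
credible CO₂ response — the qualitative pattern the method exists to
detect. Note the change-point posterior mean sits wherever the likelihood
plateau between adjacent sampled trees lies, so a small offset from truth
is expected at n = 54.

A command-line interface mirrors the stages
(`dendrocp simulate | prepare | fit-bai | fit-gnes | fit-lambda-cp |
compare-shapes | cadt`); `dendrocp simulate --out study/ --seed 1` writes a
full study directory (ring, soil, climate, CO₂ and gene-count CSVs plus a
`truth.json`) whose files feed straight back into the other subcommands.

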