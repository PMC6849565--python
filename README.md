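# traitsoil

Trait-based analysis of grassland-restoration drought experiments: from a
species × trait database and percent-cover surveys to soil
multifunctionality, drought resistance/resilience, and the plant traits
that predict them.

The package is written for ecologists analysing randomized-block
restoration experiments in which plant communities are assembled from
trait-defined functional groups and subjected to a simulated drought. It
implements the full analysis chain as tested, reusable functions, plus a
synthetic-data generator that emulates the field design (6 blocks × 7
functional-group treatments × 3 roof levels = 126 subplots) with known
ground truth, so every stage can be validated without field data.

## What it computes

- **Functional groups** — species are clustered on six standardized traits
  (canopy height, perenniality, SLA, root architectural class, rooting
  depth class, mycorrhizal affinity) with Ward linkage (a DIANA-style
  divisive alternative is available), and the classification is verified by
  linear discriminant analysis; one-way ANOVA contrasts characterise the
  trait syndromes.
- **Community trait summaries** — community-weighted means
  CWM = Σᵢ pᵢ tᵢ and functional divergence
  FDvar = (2/π)·arctan(5V), V = Σᵢ pᵢ (ln tᵢ − ln x̄)², with pᵢ the
  relative percent cover; FDvar ∈ [0, 1) and is logit-transformed for
  modelling. CO₂ fluxes are partitioned as P_syn = NEE − R_eco.
- **Soil multifunctionality** — the threshold-and-weighting score: functions
  are clustered on 1 − |Spearman ρ|, each function in a cluster of size m
  gets weight 1/(mK), and a subplot scores the weight whenever its value is
  in the top 50% of the observed distribution; the score has a maximum of 1.
- **Drought resistance and resilience** (Orwin & Wardle indices), with
  D₀ = P₀ − C₀ and Dₓ = Pₓ − Cₓ:

      RS = 1 − 2|D₀| / (C₀ + |D₀|),   RL = 2|D₀| / (|D₀| + |Dₓ|) − 1,

  both bounded in [−1, 1]; RS = 1 means no change under drought, RL = 1
  full return to the control.
- **Extreme-drought design** — a Gumbel distribution fitted to annual
  May–August maximum dry-spell lengths gives the T-year event
  x_T = μ − β·ln(−ln(1 − 1/T)).
- **Trait screening** — per function and time point, a bagged
  regression-tree ensemble ranks CWM/FDvar predictors by out-of-bag
  permutation %IncMSE; the top traits enter all-subsets mixed models
  (random intercepts for block and plot, ML fits), models with ΔAIC < 2
  are retained and coefficients are averaged with Akaike weights
  w_m = exp(−Δ_m/2)/Σ exp(−Δ_j/2).

## Worked example

```python
import traitsoil as ts

exp = ts.simulate_experiment(seed=1)          # full synthetic experiment
groups = ts.cluster_species(exp.traits, k=3)  # trait-based groups
verified = ts.verify_lda(exp.traits, groups)
print(f"LDA agreement: {verified.agreement_pct:.1f}%")

stability = ts.compute_stability(exp.pairs)
smc = stability.query("function_name == 'soil_moisture'")
print(f"mean soil-moisture resistance: {smc['resistance'].mean():.3f}")

mf = ts.multifunctionality_score(exp.panel, "July")
print(f"mean July multifunctionality: {mf.scores['score'].mean():.3f}")
```

prints

```
LDA agreement: 100.0%
mean soil-moisture resistance: 0.491
mean July multifunctionality: 0.500
```

The generated syndromes are cleanly separable, so the discriminant analysis
confirms every species' cluster; the roofs remove about a third of July
soil moisture, giving a mean soil-moisture resistance near 0.49; and with continuous function
values roughly half of all threshold crossings are hit, centring the July
multifunctionality score near 0.5.

The same stages are scriptable from the shell:

```sh
traitsoil simulate --seed 1 --out sim/
traitsoil classify-traits --traits sim/traits.csv --k 3
traitsoil resilience --pairs sim/pairs.csv
traitsoil multifunctionality --panel sim/panel.csv --time-point July
traitsoil drought-design --rain rain.csv --T 100
```

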