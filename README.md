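# hrepml

Two-stage linear mixed model GWAS for quantitative traits: a fast
restricted-maximum-likelihood (REML) single-locus scan screens the genome,
and a penalized-maximum-likelihood (PML) multi-locus model with
hierarchical normal shrinkage makes the final quantitative trait
nucleotide (QTN) calls by LOD score.  The package also ships the
simulation framework used to evaluate detection power and effect-estimate
accuracy, so method behaviour can be reproduced without any external data.

It is aimed at quantitative geneticists analysing plant, animal or human
association panels of moderate size (hundreds to a few thousand
individuals, up to a few hundred thousand markers).

## The model

**Stage 1 — single-locus screening.**  For each marker with genotype
vector *x* (coded 0/1/2 for aa/Aa/AA) the phenotype follows the linear
mixed model

    y = F b + x β + u + ε,
    β ~ N(0, σ_g²),  u ~ N(0, σ_u² Σ_u),  ε ~ N(0, σ_n² I),

where *F* is the fixed-effect design (first column all ones) and
Σ_u = G Gᵀ / m is the genomic relatedness matrix of the n×m panel.
Writing ω_g = σ_g²/σ_n² and ω_u = σ_u²/σ_n², the covariance of *y* is
σ_n² (x xᵀ ω_g + Σ_u ω_u + I).  After rotating everything by the
eigenvectors of Σ_u = Q Λ Qᵀ, the covariance becomes diagonal plus a
rank-one marker term, V = x_Q x_Qᵀ ω_g + (Λ ω̂_u + I), so each marker's
profiled restricted log-likelihood

    L_r(ω_g) = −½ log|V| − ½ log|F_Qᵀ V⁻¹ F_Q| − (n−c)/2 · log(y_Qᵀ S y_Q)

costs O(n) per evaluation (Sherman–Morrison and the matrix determinant
lemma).  ω_u is estimated once under the no-marker null.  The fitted
effect β̂ = ω̂_g x_Qᵀ S y_Q, its variance, and the Wald statistic
W = β̂²/var(β̂) ~ χ²₁ give a per-marker p-value; markers passing a loose
cutoff (default p ≤ 0.01) enter stage 2.

**Stage 2 — multi-locus shrinkage.**  The t screened markers are fitted
jointly, y = F b + Σᵢ xᵢ βᵢ + ε, with a hierarchical normal penalty on
each effect: βᵢ ~ N(μᵢ, σᵢ²) and μᵢ ~ N(0, σᵢ²/τ).  Maximising the
penalized likelihood gives closed-form coordinate updates, including the
hyperparameter fixed points μᵢ = βᵢ/(τ+1) and σᵢ² = ½βᵢ²τ/(τ+1); small
effects shrink exactly to zero.  Effects with |βᵢ| > 10⁻⁴ are scored by a
likelihood-ratio test against the model without them, reported as
LOD = LR / (2 ln 10); LOD ≥ 3 (default) is a declared QTN.

## Worked example

Inputs are plain CSV: a marker-major genotype file whose first two columns
are chromosome and bp position, a single-column phenotype, an optional
n×n kinship (computed from the genotypes when omitted) and an optional
covariate file whose first column is all ones.

```sh
hrepml assoc --genotype Genotype.csv --phenotype Phenotype.csv \
             --kinship Kinship.csv --out Results.csv --time-out Time.csv -v
```

On a demonstration panel of 60 individuals and 250 markers with one
planted QTN (effect 2.5 at chr3:18000, residual variance 1) this prints

```
screened markers: 1
chr3:18000 effect=2.7016 se=0.1339 LOD=26.73
1 marker(s) declared; results in Results.csv
```

i.e. the planted marker is the only declared call; its shrinkage-fit
effect estimate is 2.70 (truth 2.5), the standard error is the
penalized-fit value √(σ̂_n²/(xᵀx + σ̂_n²/σᵢ²)), and LOD 26.7 is far above
the 3.0 call threshold.  `Results.csv` holds the same five columns
(chromosome, position, effect, std_error, lod); `Time.csv` holds
per-stage wall times.

Simulation studies run from a small YAML config:

```sh
hrepml simulate --config design.yaml --out Summary.csv
```

with, e.g., `n_individuals: 200`, `n_markers: 2000`, `n_replicates: 10`,
`seed: 4` (the eight-QTN reference design is the default).  The summary
CSV reports per-QTN detection power (%) and the mean squared error of the
effect estimates over the replicates in which the QTN was detected
(`na` when never detected).

From Python the same pipeline is three calls:

```python
from hrepml import SimulationConfig, run_power_study

summary = run_power_study(SimulationConfig(n_replicates=50, seed=1))
print(summary.average_power)   # 68.5 (percent, at this seed)
print(round(summary.average_mse, 4))  # 0.0458
```

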