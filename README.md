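# pathlasso

Pathway-grouped latent group lasso Cox survival models, with an optional
pairwise multi-task coupling penalty that links two cancer cohorts.

## The problem

Survival models built from tumour gene expression face a few hundred
patients against tens of thousands of correlated genes.  Plain lasso-Cox
regression produces sparse but unstable gene lists; grouping genes by the
signalling pathways they sit downstream of lets the model be sparse at the
pathway level instead.  Because pathways overlap, `pathlasso` uses the
*latent* group lasso: a gene belonging to k pathways is duplicated into k
independent latent columns, so the groups become disjoint and zeroing one
pathway never silences a shared gene in another.

For a cohort with standardized expression `x_i`, event/censoring times `Y_i`
and event indicators `C_i`, the single-cohort model minimizes

    l(β) + λ Σ_g √|g| ‖β_g‖₂ ,
    l(β) = −Σ_{i:C_i=1} [ x_i·β − log Σ_{j:Y_j ≥ Y_i} exp(x_j·β) ]

over the latent coefficient vector β.  Two cohorts can be fitted jointly
with a coupling penalty

    C_μ(β¹, β²) = μ Σ_g √|g| √((A_g¹²)² + (A_g²¹)²),
    A_g^{ij} = ‖β_g^i − β_g^j·(‖β_g^i‖/‖β_g^j‖)‖ · I(‖β_g^i‖>ε) I(‖β_g^j‖>ε)

which is symmetric, vanishes when the two cohorts' per-pathway blocks are
positively proportional (the same pathway may be *differentially* predictive
without cost), and is gated off entirely for pathways inactive in either
cohort.  Optimization is Adam with a decaying step size and post-hoc group
truncation (a pathway whose coefficients all fall below 0.001 in absolute
value is set exactly to zero).

The package also ships the full evaluation protocol — Harrell concordance
(c-value), Tucker congruence of coefficients across resampled fits,
repeated 80–20 splits, cross-validated grid/random hyperparameter search,
paired t-tests and Benjamini–Hochberg FDR correction — and a synthetic
generator of paired toy cohorts with known predictive pathways, so every
component is testable without any external data.

## Worked example

```sh
python examples/02_latent_group_lasso.py
```

generates a 300-patient cohort with 500 genes in 8 overlapping pathways, of
which P1 and P2 truly drive survival, and fits the group-lasso Cox model at
λ = 0.1·λ_max:

```
latent design: 160 columns over 8 pathway blocks (gene duplication adds 35 columns)
lambda_max = 99.34 (smallest lambda zeroing every group); using lambda = 9.93
selected pathways: ['P1', 'P2'] (truth: ['P1', 'P2'])
final loss 603.65 after 2000 iterations
training c-value = 0.997 (0.5 = random ranking, 1.0 = perfect)
```

The model recovers exactly the two predictive pathways; the c-value is the
fraction of comparable patient pairs ranked consistently with their observed
event order.  `examples/03_lasso_vs_group_lasso.py` and
`examples/04_multitask_coupling.py` run the repeated-split comparison and
the coupled two-cohort protocol; `pathlasso --help` exposes the same
experiments as shell commands (`simulate`, `fit`, `evaluate`, `compare`,
`multitask`).

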