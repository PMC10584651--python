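# bbvs — Bayesian bi-level variable selection for survival GWAS

`bbvs` identifies the SNPs associated with a right-censored time-to-event
outcome when the predictors carry a natural group structure — linkage-
disequilibrium (LD) blocks or genes — and *p* far exceeds *n*.  It targets
studies like time of conversion from mild cognitive impairment to
Alzheimer's disease, where single-SNP association tests lose all power
under genome-wide multiple-testing control.

## Model

The outcome enters a log-normal accelerated failure time (AFT) model with
spike indicators on whole groups:

    log Y_i = x_i0' β0 + Σ_g γ_g x_ig' β_g + ε_i,     ε_i ~ N(0, σ²),

with γ_g ∈ {0,1} switching block *g* in or out.  Selection runs in two
stages:

**Stage 1 (group-wise).**  Conjugate priors — β0 | σ² ~ N(0, h0 σ² I), an
information-matrix (Zellner-g style) prior β_g | σ² ~ N(0, c0 σ² Σ_g) with
Σ_g = (X_g'X_g)⁻¹, σ² ~ IG(ν0/2, ν0σ0²/2) — are integrated out
analytically, leaving the augmented log-times **w** with a multivariate-t
marginal t_n(ν0, 0, σ0² H_γ), where

    H_γ = I + h0 X0X0' + c0 Σ_{g: γ_g=1} X_g Σ_g X_g'.

A Gibbs sampler alternates (i) truncated-t draws of the latent log event
time of every censored subject (data augmentation, w_i > log t_i) and
(ii) Bernoulli draws of each γ_g with success odds given by the ratio of
marginal t densities with and without the group, times the Beta-conjugate
inclusion probability p_g ~ Beta(a, b).  Posterior inclusion probabilities
p̂_g are thresholded by Bayesian-FDR control: sort the q-values 1 − p̂_g
and keep the largest prefix whose running mean stays below α.

**Stage 2 (element-wise).**  The design is reduced to the selected groups
and the censored outcomes replaced by their posterior means w̃.  A
group-indexed Dirichlet–Laplace (DL) shrinkage prior
θ_gj ~ N(0, σ² ψ_gj φ_gj² τ_g²), with exponential local scales ψ, simplex
weights φ_g ~ Dir(a_g,…,a_g), global scales τ_g ~ Gamma(q_g a_g, 1/2) and
a gridded concentration a_g, is sampled by a blocked Gibbs sweep.  Because
DL never returns exact zeros, the number of signals H is estimated by
2-means clustering of |θ| at every stored iteration (H = mode of the
signal-cluster sizes) and the H largest absolute posterior medians are
reported.

## Worked example

```python
import numpy as np
from bbvs import (SimulationConfig, simulate_dataset, Stage1Hyper,
                  run_stage1, run_stage2, ReducedDesign, compute_metrics)

cfg = SimulationConfig(n=300, G=100, censor_rate=0.3, seed=7)
data = simulate_dataset(cfg)                      # 100 LD blocks, 10 causal
design = data.to_design()

post = run_stage1(design, data.survival, Stage1Hyper(),
                  n_iter=800, burn_in=400, seed=1)
print("selected groups:", post.selected_groups)
print("FDR threshold p*: %.3f" % post.threshold)

cols = [np.flatnonzero(data.group_of == g) for g in post.selected_groups]
reduced = ReducedDesign(X0=design.X0,
                        group_X=[data.genotypes[:, c].astype(float)
                                 for c in cols])
_, sel = run_stage2(reduced, post.w_tilde, n_iter=2000, burn_in=1000, seed=2)
flat = np.concatenate(cols)
m = compute_metrics(flat[sel.selected_snps], data.causal_snps,
                    data.genotypes.shape[1], level="element")
print("H =", sel.H, " element TPR %.2f PPV %.2f" % (m.TPR, m.PPV))
```

Typical output:

```
selected groups: [ 0 11 12 24 29 31 33 41 61 93]
FDR threshold p*: 1.000
H = 67  element TPR 0.67 PPV 1.00
```

All ten causal blocks are recovered exactly (the posterior inclusion
probabilities separate to 1.0 vs 0.0, so p* = 1), and the element stage
keeps 67 SNPs, essentially all causal.

The same workflow is available from the shell:

```bash
bbvs simulate --config sim.yaml --seed 7 --out data/
bbvs stage1 --genotypes data/replicate0/genotypes.tsv \
            --blocks data/replicate0/blocks.tsv \
            --survival data/replicate0/survival.tsv \
            --iters 800 --burnin 400 --seed 1 --out run/
bbvs stage2 --genotypes data/replicate0/genotypes.tsv \
            --blocks data/replicate0/blocks.tsv \
            --survival data/replicate0/survival.tsv \
            --stage1-dir run/ --seed 2 --out run/
bbvs pipeline --config study.yaml --seed 1 --out study/
```

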