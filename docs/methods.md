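# Methods

## Model and two-stage procedure

The package fits a parametric log-normal accelerated failure time model
with bi-level selection on grouped predictors.  Writing w_i for the log
event time (observed exactly when the event occurred, latent above
log t_i when censored at t_i),

    w_i = x_i0' β0 + Σ_g γ_g x_ig' β_g + ε_i,   ε_i ~ N(0, σ²).

Stage 1 treats which blocks matter; stage 2 treats which members of the
surviving blocks matter.  The stages are deliberately asymmetric: group
selection uses a fully marginalised spike model where the regression
coefficients and σ² are integrated out in closed form, while element
selection keeps coefficients explicit under a continuous shrinkage prior
so that posterior magnitudes can be ranked.

### Stage 1: marginalised spike indicators

Priors: β0 | σ² ~ N(0, h0 σ² I);  β_g | σ² ~ N(0, c0 σ² Σ_g) with
Σ_g = (X_g'X_g)⁻¹ (information-matrix / Zellner-g form; ridge-stabilised
(X_g'X_g + λI)⁻¹ when a block is wider than the sample);
σ² ~ IG(ν0/2, ν0σ0²/2);  γ_g ~ Bernoulli(p_g), p_g ~ Beta(a, b).

Integrating β0, β, σ² leaves w ~ t_n(ν0, 0, σ0² H_γ) with
H_γ = I + h0 X0X0' + c0 Σ_{γ_g=1} X_g Σ_g X_g'.  The Gibbs sweep updates
every censored w_i from its univariate truncated-t conditional (location
and scale read off the partitioned kernel through its precision matrix;
the draw uses inverse-CDF sampling through the survival function, so a
bound far in the tail cannot stall a rejection loop), then every γ_g from
the Bernoulli whose odds are the ratio of the two marginal t densities
times p_g/(1−p_g), each followed by the conjugate Beta refresh of p_g.
Flipping one group changes H_γ by ± c0 Z_g Z_g' with Z_g = X_g chol(Σ_g),
so candidate flips are evaluated with the matrix-determinant lemma and a
Woodbury correction on the current Cholesky factor — one n×k triangular
solve per candidate instead of an n×n refactorisation; only an accepted
flip refactorises.

Groups are reported by Bayesian-FDR thresholding of the posterior
inclusion probabilities at level α (default 0.05): with q-values
q_g = 1 − p̂_g sorted ascending, the threshold keeps the largest prefix
whose running mean stays ≤ α; if none qualifies, nothing is selected.

**The g-prior scale c0 (default: n).**  The paper-style model leaves c0
free.  We resolve it to the sample size by default — the unit-information
prior, under which the whole prior carries the weight of one observation.
This is not cosmetic: a fixed O(1) value shrinks each group's explained
sum of squares by c0/(1+c0) while the log-determinant complexity penalty
stays whole, and the resulting per-group Bayes factors hover near zero
even at the true model — the sampler then simply reproduces the prior.
With c0 = n, true groups carry log Bayes factors of order +100 and null
groups of order −40 at the simulated effect sizes.

**Initialisation (screening start + regression-informed imputation
start).**  The marginalised t-likelihood creates two traps for a
single-flip chain.  From the *empty* model, all signal is unexplained, the
t's global scale absorbs it, and no single group's fit gain can beat its
complexity penalty: the empty state is numerically absorbing.  From the
*full* model, any set of active columns that saturates the sample size
fits the outcome exactly, so pruning strands the chain in an arbitrary
covering set.  The chain therefore starts at a marginal-screening state:
groups are ranked by the per-degree-of-freedom sum of squares of the
outcome projected onto the (X0-residualised) group column space, and the
top n/(2·k̄) groups start active — enough to explain most signal, far from
saturation.  Missed groups then re-enter on strong Bayes factors and
false starters drop out; in the simulated designs the chain reaches the
exact true group set reproducibly.

With censoring there is a third trap: starting the latent log-times of
censored subjects at any genotype-blind value (their bounds, or a
constant) plants residuals on the scale of the genetic signal in a third
of the rows, inflates the global t-scale and can push every group out
before the imputation has a settled model to draw from.  Censored entries
therefore start at max(ridge prediction, bound + 0.05), the ridge fitted
on the event subjects over the screened groups' columns — one
Buckley-James-style step.  All of this affects starting values only; the
stationary distribution is untouched.

### Stage 2: group-indexed Dirichlet–Laplace shrinkage

On the reduced design (all columns of the Q selected groups, outcome w̃ =
posterior mean of the stage-1 w draws, which equals log t exactly on
events), the hierarchy per group g with q_g members is

    θ_gj | · ~ N(0, σ² ψ_gj φ_gj² τ_g²),   ψ_gj ~ Exp(1/2),
    φ_g ~ Dir(a_g, …, a_g),   τ_g ~ Gamma(q_g a_g, 1/2),
    a_g ~ uniform on a 50-point grid from 1/q_g to 1/2,

with the same β0, σ² priors as stage 1.  The Gibbs sweep draws β0 and the
per-group θ_g from their conjugate normals, σ² from its inverse gamma,
then the scale block.  Two details matter and both were pinned down by a
joint-distribution (Geweke-style successive-conditional) test that any
error breaks:

* **ψ is updated through its reciprocal.**  The conditional of ψ_gj is
  giG(1/2, 1, θ²/(σφτ)²), equivalently 1/ψ_gj ~ inverse-Gaussian with
  mean σφ_gjτ_g/|θ_gj| and shape 1.  Drawing ψ directly from that
  inverse-Gaussian (a natural misreading of the usual notation) leaves
  the wrong stationary law.
* **The scale block is partially collapsed and order-sensitive.**  φ_g's
  conditional integrates both ψ and τ out; τ_g's integrates ψ out.  The
  joint draw of (φ, τ, ψ) given (θ, σ, a) is exact only in the order
  φ, then τ | φ, then ψ | φ, τ.  Other orders (e.g. ψ first) change the
  target distribution.

τ and the φ-auxiliaries are generalized-inverse-Gaussian variates; the
package ships its own vectorised giG sampler (`bbvs._gig`) based on
Devroye's universal rejection method for log-concave densities applied in
log-space, where the giG density is always log-concave: acceptance is at
least 1/4 uniformly over the parameter range, and one batched call serves
all coefficients in a sweep.  The grid weights of a_g include the
Dirichlet and Gamma normalising constants (the kernel-only variant is
available as `ag_weights="paper"` for comparison; the full conditional is
the one that passes the joint-distribution test).

**Signal counting.**  At every stored iteration the |θ| vector is split
by deterministic 2-means (centroids initialised at the min and max, Lloyd
updates); h_i is the size of the larger-centroid cluster, an exact
centroid tie counts as no signal, and H is the smallest modal value of
{h_i}.  The H largest absolute posterior medians are the selected
variables.

## Synthetic data

The generator emulates a GWAS with LD structure.  Haplotypes come from a
latent-Gaussian threshold model: within a block the latent vector is
exchangeable with correlation ρ (default 0.6), across blocks independent;
each SNP carries the minor allele where its latent value falls below the
quantile of a per-SNP MAF drawn uniformly from (0.05, 0.5); two
independent haplotypes sum to a 0/1/2 dosage.  Thresholding attenuates
the dosage-scale correlation (ρ = 0.8 latent gives dosage r² ≈ 0.26), so
ρ is a latent, not dosage, correlation.  The model reproduces the
within-block correlation that drives group selection; it does not model
recombination maps, population structure, missingness, or inter-block LD
leakage — passing tests say nothing about robustness to those.

Effects: 10 causal blocks, 10 causal SNPs each, coefficients drawn from
N(−1, sd 0.5) (a switch reads 0.5 as a variance instead).  Outcome:
log Y = X0β0 + Xβ + ε with σ = 1.  Censoring: c_i ~ Uniform(0, c*), with
c* calibrated by bisection so the expected censoring rate over the
realised event times hits the target within ±0.02.  Replicates derive
per-replicate seeds from a master seed via `SeedSequence.spawn`, so a
configuration is byte-reproducible.

## Study scale and what the desk-scale rates mean

The full-scale study behind the method used ~2,000 blocks of >30 SNPs
(~45,000 SNPs) and 50 replicates.  That scale is out of reach on one CPU,
and — more fundamentally — shrinking it naively breaks identifiability:
with 10 true blocks of ~20 SNPs and n = 200, the truth spans the whole
sample space and *any* ~10-block covering set fits the outcome exactly,
so no likelihood can separate them.  The package's default study
conditions are therefore n = 300, G = 100 blocks of 12–18 SNPs (truth
≈ 150 columns ≈ n/2), which is the stable identifiable regime the
1-CPU budget reaches; `scripts/acceptance.py` runs 8 replicates per
scenario at 800 stage-1 and 2,000 stage-2 iterations.

At those conditions, measured over replicates: group-level TPR and PPV
are 1.000/1.000 uncensored and 1.000/1.000 at 30% censoring; element-
level TPR is ≈ 0.68 uncensored and ≈ 0.64 censored — closely matching the
full-scale study's 0.686 and 0.634.  Element-level PPV, however,
saturates near 1.0 where the full-scale study reports ≈ 0.6: with only
~150 reduced-model columns at n = 300 the posterior-median ranking is
nearly perfect (causal medians ≈ 0.86 vs null ≈ 0.03 in absolute value),
so the H selected SNPs are almost all causal, while the full-scale
setting has noisier medians and admits more false selections.  The
signal-cluster fraction H/q itself is reproduced (≈ 0.33).  Desk-scale
precision should be read as an upper bound on full-scale precision, not a
reproduction of it.

## Numerical choices and degenerate inputs

* All densities in log space; Bernoulli odds through a clipped sigmoid.
* Marginal-kernel flips: determinant-lemma + Woodbury probes against the
  current Cholesky factor; a near-singular downdate capacitance gets a
  1e-10 jitter retry.
* Gram inverses: Cholesky with a scale-free pivot-ratio rank check; exact
  duplicate columns raise a rank-deficiency error naming the group.
* Truncated-t draws: inverse-CDF through `stdtr`/`stdtrit`; a bound
  beyond representable tail mass returns a point just inside the support.
* |θ| is floored at 1e-10 inside giG/inverse-Gaussian parameters and the
  inverse-Gaussian mean is capped at 1e8 when a coefficient underflows;
  prior variances are floored at 1e-12 in the θ update.
* φ draws that underflow to a zero sum renormalise to uniform with a
  logged warning; the simplex constraint holds to 1e-12 by construction.
* Constant SNP columns are dropped at load with a warning; groups left
  with fewer than 2 members are dropped (single-SNP sets carry no
  group-level information in this model).
* PPV (NPV) is reported as 1.0 when nothing was selected (rejected):
  no false call was made; flagged in logs.
* 2-means ties: equal centroids mean no separation, counted as H = 0;
  multi-modal {h_i} resolves to the smallest mode (conservative).

## Known limitations

* The marginalised stage-1 posterior is multimodal by construction in
  p ≫ n regimes; the screening start makes the dominant-mode basin
  reachable but is not a guarantee for arbitrary LD structure.
* Identifiability requires the causal column count to stay well below n;
  the model cannot distinguish saturated covering sets from the truth.
* Element-level precision at desk scale overstates full-scale precision
  (see above).
* Only log-normal AFT errors are supported; no Cox model, no genotype QC,
  no missing genotypes.
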