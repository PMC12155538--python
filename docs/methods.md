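# Methods

## The model

`coxsusie` performs Bayesian variable selection for right-censored
time-to-event outcomes over a set of p correlated candidate covariates
(genotype dosages in the fine-mapping application). The hazard for
sample i is a proportional-hazards model

    lambda_i(t) = lambda_0(t) * exp(b' x_i + c_i),

with an unknown baseline hazard `lambda_0(t)`, an optional fixed offset
`c_i`, and the sum-of-single-effects (SuSiE) prior on the coefficient
vector:

    b = sum_{l=1}^{L} b_l,     b_l = gamma_l * beta_l,
    gamma_l ~ Multinom(1, pi),   beta_l ~ N(0, sigma0l^2).

Each of the L single-effect vectors has exactly one non-zero entry, so
b has at most L non-zeros; with the default uniform pi every covariate
is a priori equally likely to carry the effect. All inference is based
on the Cox partial likelihood, so the baseline hazard never needs to be
specified and only the ranks of the observed times matter.

## Single-variable Bayes factors

The elementary computation is the Bayes factor comparing a
single-covariate Cox model (normal prior N(0, sigma0^2) on b) against
the null b = 0. The integral has no closed form; the package provides
three estimators.

* **Laplace BF** (the workhorse): replace the partial log-likelihood by
  its quadratic expansion around the MLE b-hat with curvature 1/s^2
  (s = standard error from the observed information). This gives

      log BF_lap = log ABF - z^2/2 + [log l(b-hat) - log l(0)],

  with z = b-hat/s. It needs exactly three statistics per covariate —
  b-hat, s, and the likelihood ratio — all of which come out of one
  Newton-Raphson fit.
* **ABF** (Wakefield's asymptotic BF): uses only z and s,
  `ABF = sqrt(s^2/(sigma0^2+s^2)) * exp{(z^2/2) sigma0^2/(sigma0^2+s^2)}`.
  It replaces the exact likelihood ratio with its quadratic guess
  z^2/2, and empirically overestimates the BF; it is provided for
  comparison, not used in fitting.
* **Gauss-Hermite quadrature** (gold standard, 32 nodes by default):
  integrates the exact partial likelihood against the prior. The
  integration variable is recentered at the approximate posterior mode
  mu1 and rescaled by the approximate posterior sd sigma1 before
  applying the quadrature rule. This adaptive placement matters: at
  large n the posterior is orders of magnitude narrower than the prior,
  and nodes placed under the prior itself straddle the posterior bump
  and can miss it entirely (we measured an error of 0.44 in natural-log
  BF already at n = 200 with z near 4). Prior-centered placement
  remains available via `recenter=False` for the regime where prior and
  posterior have comparable scales. Node count 32 is the default;
  doubling to 64 changes the result by < 1e-4 on our fixtures.

The posterior of the effect given the quadratic approximation is
normal with `sigma1^2 = 1/(1/s^2 + 1/sigma0^2)` and
`mu1 = (sigma1^2/s^2) b-hat` (precision-weighted shrinkage).

## Single-effect regression and the EM step

The single-effect regression (SER) posterior over which covariate is
active is a softmax: `alpha_j` proportional to `pi_j * BF_j`, computed
with max subtraction in log space so that z-scores in the hundreds
cannot overflow. The scan fits all p univariate Cox models in one
vectorized batch (see *Numerics* below), which also makes the result
independent of any execution ordering.

The prior variance sigma0^2 of an effect can be estimated by EM on the
SER's approximate marginal likelihood
`l_SER(sigma0^2) = sum_j pi_j * BF_j * l(0)`: the E-step is the SER
posterior, the M-step is `sigma0^2 <- sum_j alpha_j (mu1_j^2 +
sigma1_j^2)`. One M-step is taken per SER fit inside the outer
algorithm (not an inner EM loop) — the outer iterations themselves
provide the remaining ascent, and the alternation is verified to be
monotone in `l_SER` by the test suite. On null data the M-step contracts
toward zero; values below the floor 1e-8 are clamped and the effect is
flagged *null*. A floored effect keeps a near-uniform alpha whose
credible set is essentially the whole region; the purity filter removes
it, and null-flagged effects are excluded from PIPs and credible sets
so they cannot manufacture signal.

## gIBSS: fitting L effects

Generalized Iterative Bayesian Stepwise Selection cycles through the L
effects in index order; for effect l it removes that effect's current
posterior-mean contribution from the shared offset vector
(`c_l = c - X b-bar_l`), fits a fresh SER at offset c_l, takes one
sigma0l^2 M-step, refreshes `b-bar_l = alpha_l * mu1_l`, and restores
the offset. Fixed covariates (sex, genetic PCs, ...) are handled by a
one-time multivariate Cox fit whose linear predictor seeds the offsets;
this avoids turning the univariate integrals into (m+1)-dimensional
ones. Per-sweep cost is O(npL).

Unlike the Gaussian SuSiE coordinate ascent, this scheme has no known
objective function, so there is no ELBO to monitor. Convergence is
declared when `max_{l,j} |change in b-bar_lj|` over a full sweep drops
below `tol` (default 1e-3); the default iteration cap is 100 sweeps.
Both choices are heuristics where the algorithm itself offers no
guarantee; the stopping metric is recorded per sweep in
`SusieFit.history` for auditing. After each sweep the offset vector is
re-anchored to the exact identity `c = c_fixed + sum_l X b-bar_l` so
floating-point drift cannot accumulate across sweeps.

PIPs aggregate the per-effect inclusion probabilities as
`PIP_j = 1 - prod_l (1 - alpha_lj)` over non-null effects.

## Credible sets

A level-rho credible set for effect l is the minimal prefix of
variants, sorted by descending alpha_lj (ties broken by ascending
index), whose cumulative mass reaches rho (default 0.95; "reaches" is
`>= rho` so exact attainment terminates). Purity is the smallest
absolute pairwise Pearson correlation among members, computed on the
raw dosage columns; sets with purity below 0.5 are discarded, and a
singleton's purity is 1 by convention so the filter never removes it.
Identical member sets arising from different effects are reported once,
keeping the lowest effect index. The sentinel is the member with the
largest within-effect alpha.

## Synthetic data

The generator emulates the study conditions the method is evaluated
under:

* **Genotypes**: dosages x in {0,1,2} with marginal Binom(2, f). LD is
  emulated by thresholding a latent AR(1) Gaussian field (lag-1
  correlation `ld_rho`) at the binomial quantiles, which keeps the
  marginals exactly binomial while producing adjacent-dosage
  correlations around 0.85 at `ld_rho = 0.9`, f = 0.3 — the very
  high-LD regime that makes fine-mapping hard. This one-parameter
  copula stands in for real reference-panel LD; it produces a banded,
  stationary correlation structure and cannot reproduce the irregular
  block patterns of real haplotypes, so simulation results speak to the
  high-correlation regime generally, not to any specific locus.
* **Event times**: inverse-transform sampling from the cumulative
  hazard with an exponential baseline by default (Weibull optional).
  Since the partial likelihood only sees ranks, the baseline family
  affects nothing downstream — the package's own tests confirm rank
  invariance.
* **Censoring**: independent exponential censoring times, with the rate
  calibrated by Brent root-finding so that the *expected* censored
  fraction given the realized event times equals `target_censoring`
  (realized rates land within ±0.02 at n = 10,000). Independent
  censoring is exactly the assumption the Cox model makes; informative
  censoring is not modeled.

All randomness descends from one root seed through named child
streams; datasets are bit-reproducible.

Simulation scales used in the tests and the acceptance script — 20
single-SNP datasets at n = 10,000 for the Bayes-factor comparison, and
50 datasets at n = 2,000, p = 200 (two causal variants, |b| = 0.7,
AR(1) rho = 0.9, 20% censoring, L = 5) for credible-set coverage, with
50 null datasets at n = 1,000, p = 100 for the false-positive control —
are desk-scale analogues chosen so the full battery completes in
minutes on one core while preserving the qualitative regime (strong LD,
realistic censoring, detectable but not overwhelming effects).

## Numerical choices

* Univariate fits: Newton-Raphson from b = 0, tolerance 1e-8 on the
  gradient, at most 25 iterations, step-halving on likelihood decrease
  (compared at a relative noise floor of 1e-10, since partial
  log-likelihoods of magnitude ~1e3 cannot be compared at absolute
  1e-12). |b-hat| is capped at 15: beyond that the likelihood is
  monotone (complete separation), the fit is flagged non-converged, and
  the huge standard error makes the SER discount it naturally.
* All p columns are fitted simultaneously: samples are sorted by time
  once per outcome, risk-set sums become suffix cumulative sums over
  unique-time groups (`np.add.reduceat` + reversed cumsum), arranged
  (p, n) row-major so the reductions run over contiguous memory. Efron
  tie handling loops over the maximum tie multiplicity; with no ties it
  coincides exactly with Breslow and the loop collapses.
* Zero-variance (monomorphic) covariates take a degenerate path: b-hat
  = 0, BF = 1, alpha gets exactly the prior weight. No data, no update.
* Risk-set convention: a subject observed at time t is in the risk set
  for events at t (right-continuous risk sets).
* Linear predictors are shifted by their per-column maximum before
  exponentiation; the partial likelihood is invariant to the shift.

## Limitations

* No left truncation, competing risks, time-varying covariates or
  effects, stratified baselines, or frailty terms.
* The purity filter needs individual-level dosages; purity from an
  external LD reference panel is not implemented.
* gIBSS convergence is heuristic; on pathological inputs the iteration
  cap may bind (`converged=False` is reported, not raised).
* PIP calibration demonstrated on synthetic LD transfers to real
  genotypes only insofar as the copula's correlation structure
  resembles theirs.
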