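# Methods

## The problem

Administrative health databases (physician claims, hospital discharges)
record diagnoses collected for billing, not for epidemiology. Treating a
diagnostic code as a perfect indicator of disease biases prevalence
estimates: the observed ("apparent") prevalence `P` mixes true positives
with false positives. With sensitivity `S` (probability a true case is
coded) and specificity `C` (probability a non-case is not coded),

```
P = pi * S + (1 - pi) * (1 - C)
```

so the true prevalence is `pi = (P + C - 1) / (S + C - 1)` (the
Rogan–Gladen correction), defined whenever the code is informative
(`S + C > 1`). Even excellent codes distort badly at low prevalence: at
`P = 1%` with `S = C = 99.5%` the corrected prevalence is 0.5% — half the
naive figure.

## Models

**Single-test latent class model (k = 1).** Three parameters
(`pi, S, C`) but a single degree of freedom in the positives/total data.
The model is not identifiable: no amount of data pins down `pi` without
external information, which enters as beta prior densities on `S` and `C`
(point estimates would understate uncertainty). The posterior for `pi`
remains wide under flat priors at any sample size — this is a feature of
honest inference, not a defect.

**k-test conditional-independence latent class model.** With k binary
"clues" (diagnostic code, disease-specific prescriptions, procedure
codes), true status is a latent two-class variable and tests are assumed
independent given status. The cross-classified `2**k` table gives
`2**k - 1` degrees of freedom against `2k + 1` parameters; `k = 3` is the
smallest identifiable design (7 vs 7), and the model is then estimable
with flat priors. Conditional dependence between tests is out of scope.

**Hierarchical multi-region model.** Region prevalences are modelled
`logit(pi_r) ~ Normal(mu, tau^2)` with `S`, `C` shared across regions
(the clues are the same database fields everywhere; a region-specific
option is available through separate fits). The logit-normal form was
chosen for its unbounded scale, convenient for random-walk updates, and
because it is the standard choice in hierarchical prevalence modelling.
Hyperpriors default to `mu ~ Normal(0, 10)` (diffuse on the logit scale)
and `tau ~ Half-Normal(1)`.

## Estimation

**Gibbs sampler with data augmentation.** Each sweep imputes, per
observed pattern, the latent number of true cases from its conditional
binomial, then draws `pi` and each `(S_j, C_j)` from conjugate beta
conditionals. The likelihood has a mirror mode (`S -> 1 - C`,
`C -> 1 - S`, `pi -> 1 - pi`); it is removed by constraining every
retained draw to `S_j + C_j > 1`, sampled by rejection against the
unconstrained beta with an exact inverse-CDF truncated draw as fallback
after 64 misses (never a stall, never a biased draw).

**Ridge refresh.** For weakly identified fits (k < 3) the conjugate
moves creep along the non-identified ridge in steps of order
`n**-0.5`, so the augmentation chain alone mixes in O(n) sweeps. Each
sweep therefore ends with a collapsed independence-Metropolis step:
propose `(pi, S, C)` fresh from the (constraint-rejected) joint prior and
accept with the marginal likelihood ratio — with a prior proposal the
Hastings ratio reduces to exactly that. Accepted refreshes jump anywhere
on the ridge; the single-test sampler then matches a 200^3 lattice
integration of the exact posterior (checked in the tests). For
identifiable fits the step is almost never accepted and costs one
likelihood evaluation.

**Hierarchical sampler.** Alternates the same latent-count augmentation
(all regions at once) with: conjugate truncated-beta updates for the
shared `S_j, C_j` pooling latent counts over regions; random-walk
Metropolis on each `logit(pi_r)` given the region's latent true-case
count; a conjugate normal update for `mu`; and a random-walk update on
`log(tau)` with the Jacobian term. Step sizes are tuned every 50
proposals during burn-in toward a 0.2–0.5 acceptance band and frozen
after burn-in (tuning after burn-in would break detailed balance).
Chains whose post-burn-in acceptance leaves [0.05, 0.95] are flagged
with a warning, never silently dropped.

**EM cross-check.** The same likelihood is maximised by EM (E-step:
posterior class membership per pattern; M-step: weighted proportions),
with a moment-based start plus five jittered restarts keeping the best
log-likelihood, since the surface can be multimodal. The solution is
relabeled through the mirror map when that makes more tests informative.
With flat priors and large n the Gibbs posterior means and the EM MLE
agree to well under 0.01 — the Bayesian and frequentist routes coincide
when the prior carries no information.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| priors | Beta(1, 1) everywhere | minimum-information; override per parameter |
| `n_iter` | 20000 | sweeps per chain |
| `burn_in` | 5000 | discarded sweeps |
| `n_chains` | 4 | independent chains, dispersed starts |
| `thin` | 1 | keep every draw |
| `seed` | **required** | no silent default; chain c uses `SeedSequence([seed, c])` |
| EM `tol` | 1e-8 | stop when log-likelihood gain falls below |
| EM `max_iter` | 10000 | returns best iterate with `converged=False` beyond |
| `mu_prior` | Normal(0, 10) | population logit-mean |
| `tau_prior` | Half-Normal(1) | population logit-spread |

All probabilities are unitless proportions in [0, 1]; `mu`, `tau` live on
the logit scale.

## Numerical choices and degenerate inputs

- Observed `P` outside the feasible band `[1 - C, S]` (possible by
  sampling noise): the closed-form correction clamps to [0, 1] and warns
  rather than erroring — the Bayesian models are the recommended path in
  that regime. `S + C = 1` exactly is an error (the estimand is
  undefined), not a clamp.
- Zero cells need no continuity correction; beta-binomial conjugacy
  handles them.
- A pattern observed with zero model probability makes the log-likelihood
  `-inf`, returned with a warning, never masked.
- R-hat is the classic between/within-chain potential scale reduction
  `sqrt(((n-1)/n W + B/n) / W)`. With identical chains `B = 0` and the
  estimator equals `sqrt((n-1)/n)`, i.e. 1 up to O(1/n) from below; it is
  reported as NaN (unavailable) for a single chain, never fabricated.
  Effective sample size uses Geyer's initial positive sequence: lag
  autocorrelations (FFT) summed in adjacent pairs, truncated at the first
  negative pair sum, capped at the number of retained draws.
- Pattern order is fixed everywhere: test 1 is the most significant bit,
  1 = positive, so for three tests index 5 = "101".

## Synthetic data

`simulate_panel` draws individual true statuses `Bernoulli(pi)` and then
each test given status — exactly the conditional-independence structure
the models assume (a multinomial shortcut over pattern probabilities is
provided and tested for distributional equivalence).
`simulate_regions` draws region prevalences logit-normally and simulates
each region's panel with a deterministically derived seed.

Because generator and model share their structure, passing recovery and
coverage tests demonstrates *internal* correctness of the estimators —
that the samplers target the stated posterior and the intervals have
their nominal frequentist behaviour under the model. It does not
validate the conditional-independence assumption, the constancy of S and
C across regions, or the absence of claims-stream artifacts (coding
drift, repeat billing) in any real database.

Reference operating points used throughout the tests: a 10% prevalence
condition read by three clues with `S = (0.90, 0.85, 0.80)`,
`C = (0.95, 0.90, 0.97)` — moderately good administrative indicators —
and the single-code point `P = 1%`, `S = C = 99.5%`.

## Problem sizes in the test suite

The suite favours designs whose Monte Carlo error is far below the
tolerance being asserted: Bayesian/frequentist agreement uses one panel
of n = 100 000 with 2 chains x 6000 sweeps; interval coverage uses 100
replicates at n = 20 000 with single 1500-sweep chains; hierarchical
hypermean coverage uses 30 replicates of 8 regions at n = 5000. These
sizes are the package's choice of a design where the checked asymptotics
have set in while the suite stays quick to run.

## Known limitations

- Conditional dependence between tests is not modelled; correlated clues
  (e.g. a prescription triggered by the diagnosis code) bias all k-test
  fits, typically optimistically.
- Two latent classes only; no disease subtypes or severity grades.
- No spatial correlation between regions (CAR/ICAR) and no covariate
  regression on prevalence.
- The non-identifiable model's answer is only as good as its priors; the
  package quantifies that honestly (wide intervals) but cannot repair it.
- Closed-form correction reports a point value only; interval estimation
  is deliberately delegated to the Bayesian models.
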