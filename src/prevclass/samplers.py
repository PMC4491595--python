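"""Bayesian estimation for prevalence under imperfect ascertainment.

Two latent class models over k conditionally independent binary tests:

* the non-identifiable single-test model (k = 1): three parameters
  (prevalence pi, sensitivity S, specificity C) against one degree of
  freedom, so inference leans on informative priors — only a Bayesian
  analysis gives reasonable answers here;
* the identifiable k-test model (k >= 3): 2k + 1 parameters against
  2**k - 1 degrees of freedom, estimable from the cross-classified table
  alone, with flat "minimum information" priors as the default.

Both are fit by data-augmentation Gibbs sampling with conjugate beta
updates: each sweep imputes, per observed outcome pattern, the latent
number of true cases from its conditional binomial, then draws pi, each
S_j and each C_j from beta conditionals.  The mirror mode of the
likelihood (S -> 1 - C, C -> 1 - S, pi -> 1 - pi) is removed by
constraining every retained draw to S_j + C_j > 1, the convention that
tests are informative; the constrained conditionals are sampled by
rejection with an exact inverse-CDF truncated-beta fallback.

An EM maximum-likelihood fitter for the same likelihood is provided as a
frequentist cross-check: with flat priors and large n the posterior means
and the MLE agree numerically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    InvalidInputError,
    MisclassParams,
    TestPanelCounts,
    WrongModelError,
    pattern_matrix,
)

# Beyond this many rejected (S_j, C_j) proposals the truncated conditional is
# sampled exactly by inverse-CDF instead.
_MAX_REJECT = 64


# ---------------------------------------------------------------------------
# Priors and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior for a probability parameter."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidInputError(
                f"beta prior needs alpha, beta > 0, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


FLAT = BetaPrior(1.0, 1.0)


@dataclass(frozen=True)
class ModelPriors:
    """Beta priors for prevalence and for every test's sensitivity/specificity."""

    pi_prior: BetaPrior
    S_priors: tuple
    C_priors: tuple

    def __post_init__(self):
        object.__setattr__(self, "S_priors", tuple(self.S_priors))
        object.__setattr__(self, "C_priors", tuple(self.C_priors))
        if len(self.S_priors) != len(self.C_priors) or len(self.S_priors) < 1:
            raise InvalidInputError("S_priors and C_priors must have equal length k >= 1")
        for p in (self.pi_prior, *self.S_priors, *self.C_priors):
            if not isinstance(p, BetaPrior):
                raise InvalidInputError(f"expected BetaPrior, got {type(p).__name__}")

    @property
    def k(self) -> int:
        return len(self.S_priors)

    @classmethod
    def flat(cls, k: int) -> "ModelPriors":
        """Minimum-information Beta(1, 1) priors on every parameter."""
        return cls(FLAT, (FLAT,) * k, (FLAT,) * k)


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs sampler settings.  A seed is required; there is no silent default."""

    seed: int
    n_iter: int = 20000
    burn_in: int = 5000
    n_chains: int = 4
    thin: int = 1

    def __post_init__(self):
        if self.n_iter < 1 or self.n_chains < 1 or self.thin < 1:
            raise InvalidInputError("n_iter, n_chains and thin must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise InvalidInputError("need 0 <= burn_in < n_iter")
        if self.n_kept < 1:
            raise InvalidInputError("configuration retains no draws")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def param_names(k: int, region_ids=None) -> list:
    """Canonical parameter ordering: pi (or per-region pi's), S_1..S_k, C_1..C_k."""
    if region_ids is None:
        head = ["pi"]
    else:
        head = [f"pi_{r}" for r in region_ids]
    return head + [f"S_{j}" for j in range(1, k + 1)] + [f"C_{j}" for j in range(1, k + 1)]


@dataclass(frozen=True)
class PosteriorDraws:
    """Labeled MCMC draws, indexed (chain, iteration, parameter)."""

    names: tuple
    draws: np.ndarray
    config: McmcConfig

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 3 or draws.shape[2] != len(self.names):
            raise InvalidInputError(
                f"draws must be (chains, iterations, {len(self.names)}), got {draws.shape}"
            )
        object.__setattr__(self, "draws", draws)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def param(self, name: str) -> np.ndarray:
        """All draws of one parameter, shape (chains, iterations)."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no parameter named {name!r}; have {self.names}") from None
        return self.draws[:, :, j]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled across chains."""
        return self.param(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with chain and iteration columns."""
        n_c, n_i, _ = self.draws.shape
        frame = pd.DataFrame(
            self.draws.reshape(n_c * n_i, -1), columns=list(self.names)
        )
        frame.insert(0, "iteration", np.tile(np.arange(n_i), n_c))
        frame.insert(0, "chain", np.repeat(np.arange(n_c), n_i))
        return frame


def chain_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic sub-stream for chain / region / replicate `index`.

    Sub-streams are spawned as ``SeedSequence([master_seed, index])`` so that
    every (seed, index) pair maps to a fixed, platform-independent generator
    state.
    """
    return np.random.SeedSequence([int(master_seed), int(index)])


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def cell_probabilities(params: MisclassParams) -> np.ndarray:
    """Model probability of each of the 2**k outcome patterns.

    Conditional independence given true status: a true case is positive on
    test j with probability S_j, a non-case with probability 1 - C_j.
    """
    B = pattern_matrix(params.k)
    pos = np.where(B == 1, params.S[None, :], 1.0 - params.S[None, :]).prod(axis=1)
    neg = np.where(B == 1, 1.0 - params.C[None, :], params.C[None, :]).prod(axis=1)
    return params.pi * pos + (1.0 - params.pi) * neg


def lca_loglik(counts: TestPanelCounts, params: MisclassParams) -> float:
    """Latent class log-likelihood of the cross-classified counts.

    Returns -inf (with a warning) when a pattern with positive count has
    zero model probability.
    """
    if params.k != counts.k:
        raise WrongModelError(
            f"params have k={params.k} tests but counts have k={counts.k}"
        )
    probs = cell_probabilities(params)
    observed = counts.counts > 0
    if np.any(probs[observed] == 0.0):
        warnings.warn(
            "zero-probability pattern observed with positive count; log-likelihood is -inf",
            UserWarning,
            stacklevel=2,
        )
        return float("-inf")
    return float(np.sum(counts.counts[observed] * np.log(probs[observed])))


# ---------------------------------------------------------------------------
# Gibbs samplers
# ---------------------------------------------------------------------------

def _truncated_beta(rng: np.random.Generator, a: float, b: float, lower: float) -> float:
    """Draw Beta(a, b) conditioned on exceeding `lower`.

    Rejection from the unconstrained beta (fast when the posterior mass sits
    above the bound, the usual case for informative tests), falling back to
    exact inverse-CDF sampling after _MAX_REJECT misses.
    """
    if lower <= 0.0:
        return float(rng.beta(a, b))
    for _ in range(_MAX_REJECT):
        x = rng.beta(a, b)
        if x > lower:
            return float(x)
    # Exact truncated draw: invert the CDF above the bound.
    lo_cdf = stats.beta.cdf(lower, a, b)
    u = lo_cdf + rng.random() * (1.0 - lo_cdf)
    return float(min(np.nextafter(1.0, 0.0), stats.beta.ppf(u, a, b)))


def _init_state(k: int, rng: np.random.Generator):
    """Dispersed start inside the constraint region S_j + C_j > 1."""
    pi = rng.uniform(0.05, 0.95)
    S = rng.uniform(0.55, 0.99, size=k)
    C = rng.uniform(0.55, 0.99, size=k)
    return pi, S, C


def _cell_loglik(counts_vec, B, pi, S, C) -> float:
    pos = np.where(B == 1, S[None, :], 1.0 - S[None, :]).prod(axis=1)
    neg = np.where(B == 1, 1.0 - C[None, :], C[None, :]).prod(axis=1)
    probs = pi * pos + (1.0 - pi) * neg
    obs = counts_vec > 0
    if np.any(probs[obs] <= 0.0):
        return float("-inf")
    return float(np.sum(counts_vec[obs] * np.log(probs[obs])))


def _prior_draw(priors: ModelPriors, rng: np.random.Generator, max_tries: int = 256):
    """Rejection draw of (pi, S, C) from the joint prior restricted to S_j + C_j > 1.

    Plain rejection keeps the proposal exactly proportional to the
    constrained prior, so the independence-Metropolis ratio stays a pure
    likelihood ratio.  Returns None if the constraint is too improbable
    under the priors (the refresh move is then skipped for the sweep).
    """
    pi = rng.beta(priors.pi_prior.alpha, priors.pi_prior.beta)
    S = np.empty(priors.k)
    C = np.empty(priors.k)
    for j, (ps, pc) in enumerate(zip(priors.S_priors, priors.C_priors)):
        for _ in range(max_tries):
            s = rng.beta(ps.alpha, ps.beta)
            c = rng.beta(pc.alpha, pc.beta)
            if s + c > 1.0:
                S[j], C[j] = s, c
                break
        else:
            return None
    return pi, S, C


def _gibbs_chain(counts_vec, B, priors: ModelPriors, config: McmcConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """One chain of the data-augmentation Gibbs sampler.

    Each sweep: (1) for each pattern, impute the latent count of true cases
    from Binomial(count, w_pattern) where w is the conditional class
    probability; (2) conjugate beta updates for pi and each (S_j, C_j) pair,
    the pair truncated to S_j + C_j > 1; (3) a collapsed
    independence-Metropolis refresh — propose (pi, S, C) from the priors
    and accept with the marginal (latent-free) likelihood ratio.  The
    refresh is what keeps weakly identified posteriors (k < 3) mixing: the
    conjugate moves only creep along the non-identified ridge in steps of
    order n**-0.5, while an accepted refresh jumps anywhere on it.  The
    note on the proposal-from-prior ratio: with proposal q = prior, the
    Hastings ratio reduces to the likelihood ratio.
    """
    k = B.shape[1]
    n = int(counts_vec.sum())
    a_pi, b_pi = priors.pi_prior.alpha, priors.pi_prior.beta
    aS = np.array([p.alpha for p in priors.S_priors])
    bS = np.array([p.beta for p in priors.S_priors])
    aC = np.array([p.alpha for p in priors.C_priors])
    bC = np.array([p.beta for p in priors.C_priors])

    pi, S, C = _init_state(k, rng)
    out = np.empty((config.n_kept, 2 * k + 1))
    kept = 0
    for it in range(config.n_iter):
        # Latent true-case counts per pattern.
        pos = np.where(B == 1, S[None, :], 1.0 - S[None, :]).prod(axis=1)
        neg = np.where(B == 1, 1.0 - C[None, :], C[None, :]).prod(axis=1)
        num = pi * pos
        den = num + (1.0 - pi) * neg
        w = np.divide(num, den, out=np.full_like(num, 0.5), where=den > 0)
        z = rng.binomial(counts_vec, w)

        n_true = int(z.sum())
        pi = rng.beta(a_pi + n_true, b_pi + n - n_true)

        pos_true = B.T @ z                      # true cases positive on test j
        pos_false = B.T @ (counts_vec - z)      # non-cases positive on test j
        n_false = n - n_true
        for j in range(k):
            S[j] = _truncated_beta(
                rng, aS[j] + pos_true[j], bS[j] + n_true - pos_true[j], 1.0 - C[j]
            )
            C[j] = _truncated_beta(
                rng, aC[j] + n_false - pos_false[j], bC[j] + pos_false[j], 1.0 - S[j]
            )

        # Collapsed ridge-refresh move (see docstring).
        proposal = _prior_draw(priors, rng)
        if proposal is not None:
            ll_prop = _cell_loglik(counts_vec, B, *proposal)
            ll_cur = _cell_loglik(counts_vec, B, pi, S, C)
            if math.log(rng.random()) < ll_prop - ll_cur:
                pi, S, C = proposal

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out[kept, 0] = pi
            out[kept, 1:k + 1] = S
            out[kept, k + 1:] = C
            kept += 1
    return out[:kept]


def lca_gibbs(counts: TestPanelCounts, priors: ModelPriors,
              config: McmcConfig) -> PosteriorDraws:
    """Fit the k-test conditional-independence latent class model by Gibbs.

    Runs ``config.n_chains`` independent chains from dispersed starts, each
    seeded deterministically from ``config.seed`` and the chain index.
    Retained draws satisfy S_j + C_j > 1 for every test (label-switching
    constraint).
    """
    if priors.k != counts.k:
        raise InvalidInputError(
            f"priors have k={priors.k} but counts have k={counts.k}"
        )
    if counts.n < 1:
        raise InvalidInputError("empty panel cannot be fit")
    B = pattern_matrix(counts.k)
    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seed(config.seed, c))
        chains.append(_gibbs_chain(counts.counts, B, priors, config, rng))
    return PosteriorDraws(
        names=param_names(counts.k), draws=np.stack(chains), config=config
    )


def single_test_gibbs(counts: TestPanelCounts, priors: ModelPriors,
                      config: McmcConfig) -> PosteriorDraws:
    """Fit the non-identifiable single-test model (k = 1) by Gibbs.

    Three parameters against one degree of freedom: the posterior for the
    prevalence never concentrates to a point, however large n; informative
    priors on S and C are what carry the inference.  The sampler is the
    k = 1 specialization of :func:`lca_gibbs` — the augmentation splits
    test-positives and test-negatives into their latent true-case parts.
    """
    if counts.k != 1:
        raise WrongModelError(
            f"single_test_gibbs requires k = 1 counts, got k = {counts.k}"
        )
    return lca_gibbs(counts, priors, config)


# ---------------------------------------------------------------------------
# EM maximum likelihood
# ---------------------------------------------------------------------------

def _em_step(counts_vec: np.ndarray, B: np.ndarray, pi: float,
             S: np.ndarray, C: np.ndarray):
    """One EM iteration on (possibly fractional) pattern counts.

    E-step: per-pattern posterior probability of the true-case class.
    M-step: prevalence and per-test rates as weighted proportions.
    """
    pos = np.where(B == 1, S[None, :], 1.0 - S[None, :]).prod(axis=1)
    neg = np.where(B == 1, 1.0 - C[None, :], C[None, :]).prod(axis=1)
    num = pi * pos
    den = num + (1.0 - pi) * neg
    w = np.divide(num, den, out=np.full_like(num, 0.5), where=den > 0)

    n = counts_vec.sum()
    n_true = float(counts_vec @ w)
    n_false = n - n_true
    pi_new = n_true / n
    with np.errstate(invalid="ignore"):
        S_new = (B.T @ (counts_vec * w)) / n_true if n_true > 0 else S.copy()
        C_new = 1.0 - (B.T @ (counts_vec * (1.0 - w))) / n_false if n_false > 0 else C.copy()
    return float(pi_new), np.clip(S_new, 0.0, 1.0), np.clip(C_new, 0.0, 1.0)


def _mirror(pi, S, C):
    # Swapping class labels leaves the likelihood unchanged.
    return 1.0 - pi, 1.0 - C, 1.0 - S


def _loglik_arrays(counts_vec, B, pi, S, C) -> float:
    pos = np.where(B == 1, S[None, :], 1.0 - S[None, :]).prod(axis=1)
    neg = np.where(B == 1, 1.0 - C[None, :], C[None, :]).prod(axis=1)
    probs = pi * pos + (1.0 - pi) * neg
    obs = counts_vec > 0
    if np.any(probs[obs] <= 0.0):
        return float("-inf")
    return float(np.sum(counts_vec[obs] * np.log(probs[obs])))


def _moment_init(counts: TestPanelCounts) -> MisclassParams:
    """Moment-based start from marginal positivity rates.

    Assumes moderately good tests (S ~ 0.8, C ~ 0.9) and backs the starting
    prevalence out of the mean marginal positivity with the closed-form
    inversion; clipped well inside (0, 1).
    """
    B = pattern_matrix(counts.k)
    marg = (B.T @ counts.counts) / counts.n
    S0 = np.full(counts.k, 0.8)
    C0 = np.full(counts.k, 0.9)
    pi0 = float(np.clip((marg.mean() + 0.9 - 1.0) / 0.7, 0.05, 0.95))
    return MisclassParams(pi=pi0, S=S0, C=C0)


def lca_em(counts: TestPanelCounts, init: MisclassParams | None = None,
           tol: float = 1e-8, max_iter: int = 10000, n_starts: int = 5,
           allow_underidentified: bool = False, seed: int = 0):
    """Maximum-likelihood fit of the latent class model by EM with multi-start.

    The likelihood can be multimodal, so in addition to `init` (moment-based
    when omitted) the fitter runs `n_starts` jittered restarts and keeps the
    best log-likelihood.  The solution is relabeled via the mirror map so
    that the tests come out informative (S_j + C_j > 1).

    Returns ``(params, loglik, n_iters, converged)``; for k < 3 the model is
    not identifiable from the data and the fit is refused unless
    `allow_underidentified` is set.
    """
    if counts.k < 3 and not allow_underidentified:
        raise WrongModelError(
            f"k = {counts.k} < 3 is not identifiable; pass allow_underidentified=True "
            "to fit anyway (results depend on the start)"
        )
    if counts.n < 1:
        raise InvalidInputError("empty panel cannot be fit")
    if init is None:
        init = _moment_init(counts)
    if init.k != counts.k:
        raise InvalidInputError(f"init has k={init.k} but counts have k={counts.k}")
    if not (0 < init.pi < 1) or np.any(init.S <= 0) or np.any(init.S >= 1) \
            or np.any(init.C <= 0) or np.any(init.C >= 1):
        raise InvalidInputError("init must lie strictly inside (0, 1)")

    B = pattern_matrix(counts.k)
    counts_vec = counts.counts.astype(float)
    rng = np.random.default_rng(chain_seed(seed, 0))

    starts = [(init.pi, init.S.copy(), init.C.copy())]
    for _ in range(n_starts):
        starts.append((
            rng.uniform(0.05, 0.95),
            rng.uniform(0.55, 0.99, counts.k),
            rng.uniform(0.55, 0.99, counts.k),
        ))

    best = None
    for pi, S, C in starts:
        ll_prev = _loglik_arrays(counts_vec, B, pi, S, C)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            pi, S, C = _em_step(counts_vec, B, pi, S, C)
            ll = _loglik_arrays(counts_vec, B, pi, S, C)
            if ll - ll_prev < tol:
                ll_prev = ll
                converged = True
                break
            ll_prev = ll
        if best is None or ll_prev > best[0]:
            best = (ll_prev, pi, S, C, it, converged)

    ll, pi, S, C, it, converged = best
    # Relabel so tests are informative; the mirror map flips every pair, so
    # use it when it increases the number of pairs satisfying the constraint.
    if np.sum(S + C > 1.0) < np.sum((1.0 - C) + (1.0 - S) > 1.0):
        pi, S, C = _mirror(pi, S, C)
    params = MisclassParams(pi=pi, S=S, C=C)
    return params, ll, it, converged
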