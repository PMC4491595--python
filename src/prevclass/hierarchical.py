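"""Multi-region prevalence estimation: separate fits and partial pooling.

When prevalence is wanted for several sub-areas (districts, catchment
areas) there are two natural designs:

* **separate fits** — an independent latent class model per region, each
  using only that region's table: unbiased by other regions but noisy
  where regions are small;
* **one hierarchical model** — region prevalences drawn from a shared
  logit-normal population distribution with unknown mean and spread,
  sensitivities and specificities shared across regions (the tests are
  the same database fields everywhere).  Pooling trades a little bias for
  precision: small regions are shrunk toward the population mean.

The hierarchical sampler alternates the same latent-count augmentation as
the single-panel Gibbs with (a) conjugate truncated-beta updates for the
shared S_j, C_j pooling latent counts over regions, (b) random-walk
Metropolis updates for each region's logit-prevalence, (c) a conjugate
normal update for the population logit-mean and a random-walk update on
the log of the population spread.  Random-walk step sizes are auto-tuned
during burn-in to a 0.2-0.5 acceptance band and frozen afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import InvalidInputError, TestPanelCounts, pattern_matrix
from .samplers import (
    BetaPrior,
    McmcConfig,
    ModelPriors,
    PosteriorDraws,
    _truncated_beta,
    chain_seed,
    lca_gibbs,
    param_names,
)


@dataclass(frozen=True)
class RegionPanel:
    """A region label paired with its cross-classified counts."""

    region_id: str
    counts: TestPanelCounts


@dataclass(frozen=True)
class NormalPrior:
    """Normal(mean, sd) prior, used for the population logit-mean."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise InvalidInputError(f"normal prior sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class HalfNormalPrior:
    """Half-normal(scale) prior on a positive scale parameter."""

    scale: float

    def __post_init__(self):
        if not self.scale > 0:
            raise InvalidInputError(f"half-normal scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class HierarchicalPriors:
    """Hyperpriors for the logit-normal population distribution plus shared test priors.

    Defaults: diffuse Normal(0, 10) on the logit-scale mean (covers
    prevalences from ~e-9 to ~1-e-9) and Half-Normal(1) on the logit-scale
    spread (a priori most regions within a factor ~e of each other on the
    odds scale).
    """

    S_priors: tuple
    C_priors: tuple
    mu_prior: NormalPrior = NormalPrior(0.0, 10.0)
    tau_prior: HalfNormalPrior = HalfNormalPrior(1.0)

    def __post_init__(self):
        object.__setattr__(self, "S_priors", tuple(self.S_priors))
        object.__setattr__(self, "C_priors", tuple(self.C_priors))
        if len(self.S_priors) != len(self.C_priors) or len(self.S_priors) < 1:
            raise InvalidInputError("S_priors and C_priors must have equal length k >= 1")

    @property
    def k(self) -> int:
        return len(self.S_priors)

    @classmethod
    def flat(cls, k: int) -> "HierarchicalPriors":
        flat = BetaPrior(1.0, 1.0)
        return cls(S_priors=(flat,) * k, C_priors=(flat,) * k)


def _check_panels(panels) -> int:
    if not panels:
        raise InvalidInputError("at least one region panel is required")
    k = panels[0].counts.k
    ids = set()
    for p in panels:
        if p.counts.k != k:
            raise InvalidInputError("all region panels must share the same k")
        if p.region_id in ids:
            raise InvalidInputError(f"duplicate region id {p.region_id!r}")
        ids.add(p.region_id)
    return k


# ---------------------------------------------------------------------------
# Separate fits
# ---------------------------------------------------------------------------

def fit_separate(panels, priors: ModelPriors, config: McmcConfig) -> dict:
    """Independent latent class Gibbs fit per region.

    Each region's chains are seeded deterministically from ``config.seed``
    and the region's position in `panels`, so one region's fit is identical
    to running :func:`~prevclass.samplers.lca_gibbs` on that panel with the
    derived seed.  Failures in one region are warned about and skipped, not
    fatal; an error is raised only if every region fails.
    """
    _check_panels(panels)
    results: dict = {}
    failures = {}
    for r, panel in enumerate(panels):
        derived = int(chain_seed(config.seed, r).generate_state(1)[0] % (2 ** 31))
        try:
            results[panel.region_id] = lca_gibbs(
                panel.counts, priors, McmcConfig(
                    seed=derived, n_iter=config.n_iter, burn_in=config.burn_in,
                    n_chains=config.n_chains, thin=config.thin,
                )
            )
        except Exception as exc:  # collected, not fatal
            failures[panel.region_id] = exc
            warnings.warn(f"region {panel.region_id!r} failed to fit: {exc}",
                          UserWarning, stacklevel=2)
    if not results:
        raise InvalidInputError(f"every region failed to fit: {failures}")
    return results


# ---------------------------------------------------------------------------
# Hierarchical fit
# ---------------------------------------------------------------------------

class _StepTuner:
    """Robbins-Monro-flavoured step-size tuning toward a 0.2-0.5 acceptance band."""

    def __init__(self, step: float = 0.5, interval: int = 50):
        self.step = step
        self.interval = interval
        self.accepted = 0
        self.proposed = 0

    def update(self, accepted: bool, tuning: bool):
        self.proposed += 1
        self.accepted += accepted
        if tuning and self.proposed % self.interval == 0:
            rate = self.accepted / self.proposed
            if rate < 0.2:
                self.step *= 0.8
            elif rate > 0.5:
                self.step *= 1.25
            self.accepted = 0
            self.proposed = 0

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else float("nan")


def _hier_chain(counts_mat, ns, B, hpriors: HierarchicalPriors,
                config: McmcConfig, rng: np.random.Generator):
    """One chain of the hierarchical sampler. counts_mat is (regions, 2**k)."""
    n_regions, n_pat = counts_mat.shape
    k = B.shape[1]
    aS = np.array([p.alpha for p in hpriors.S_priors])
    bS = np.array([p.beta for p in hpriors.S_priors])
    aC = np.array([p.alpha for p in hpriors.C_priors])
    bC = np.array([p.beta for p in hpriors.C_priors])
    m0, s0 = hpriors.mu_prior.mean, hpriors.mu_prior.sd
    tau_scale = hpriors.tau_prior.scale

    theta = rng.normal(-2.0, 1.0, size=n_regions)   # logit prevalences
    mu = float(rng.normal(-2.0, 1.0))
    tau = float(abs(rng.normal(0.0, 0.5))) + 0.05
    S = rng.uniform(0.55, 0.99, size=k)
    C = rng.uniform(0.55, 0.99, size=k)

    theta_tuner = _StepTuner(step=0.5)
    tau_tuner = _StepTuner(step=0.5)

    n_params = n_regions + 2 * k + 2
    out = np.empty((config.n_kept, n_params))
    kept = 0
    for it in range(config.n_iter):
        tuning = it < config.burn_in
        pis = expit(theta)

        # Latent true-case counts, all regions at once.
        pos = np.where(B == 1, S[None, :], 1.0 - S[None, :]).prod(axis=1)
        neg = np.where(B == 1, 1.0 - C[None, :], C[None, :]).prod(axis=1)
        num = pis[:, None] * pos[None, :]
        den = num + (1.0 - pis)[:, None] * neg[None, :]
        w = np.divide(num, den, out=np.full_like(num, 0.5), where=den > 0)
        z = rng.binomial(counts_mat, w)

        z_tot = z.sum(axis=1)                      # true cases per region
        n_true = int(z_tot.sum())
        n_false = int(ns.sum()) - n_true
        pos_true = (B.T @ z.sum(axis=0))
        pos_false = (B.T @ (counts_mat - z).sum(axis=0))
        for j in range(k):
            S[j] = _truncated_beta(
                rng, aS[j] + pos_true[j], bS[j] + n_true - pos_true[j], 1.0 - C[j]
            )
            C[j] = _truncated_beta(
                rng, aC[j] + n_false - pos_false[j], bC[j] + pos_false[j], 1.0 - S[j]
            )

        # Region logit-prevalences: random-walk Metropolis given latent counts.
        prop = theta + theta_tuner.step * rng.standard_normal(n_regions)
        def binom_logpost(th):
            # z_tot successes of ns with p = expit(th), plus logit-normal prior
            return (z_tot * th - ns * np.logaddexp(0.0, th)
                    - 0.5 * ((th - mu) / tau) ** 2)
        log_alpha = binom_logpost(prop) - binom_logpost(theta)
        accept = np.log(rng.random(n_regions)) < log_alpha
        theta = np.where(accept, prop, theta)
        for a in accept:
            theta_tuner.update(bool(a), tuning)

        # Population mean: conjugate normal update.
        prec = n_regions / tau ** 2 + 1.0 / s0 ** 2
        mean = (theta.sum() / tau ** 2 + m0 / s0 ** 2) / prec
        mu = float(rng.normal(mean, 1.0 / math.sqrt(prec)))

        # Population spread: random walk on log(tau), half-normal prior.
        lam = math.log(tau)
        lam_prop = lam + tau_tuner.step * rng.standard_normal()
        tau_prop = math.exp(lam_prop)

        def tau_logpost(t, l):
            return (-n_regions * l - 0.5 * np.sum((theta - mu) ** 2) / t ** 2
                    - 0.5 * (t / tau_scale) ** 2 + l)  # + l is the Jacobian

        acc = math.log(rng.random()) < tau_logpost(tau_prop, lam_prop) - tau_logpost(tau, lam)
        if acc:
            tau = tau_prop
        tau_tuner.update(acc, tuning)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out[kept, :n_regions] = expit(theta)
            out[kept, n_regions:n_regions + k] = S
            out[kept, n_regions + k:n_regions + 2 * k] = C
            out[kept, -2] = mu
            out[kept, -1] = tau
            kept += 1
    return out[:kept], theta_tuner, tau_tuner


def fit_hierarchical(panels, hpriors: HierarchicalPriors,
                     config: McmcConfig) -> PosteriorDraws:
    """Fit all regions jointly with a logit-normal population distribution.

    Parameters in the returned draws: ``pi_<region_id>`` for each region,
    the shared ``S_1..S_k`` and ``C_1..C_k``, and the hyperparameters
    ``mu`` (population logit-mean) and ``tau`` (population logit-spread).
    With a single panel the model degenerates to a fixed-effect fit of that
    panel.  Chains whose random-walk acceptance left the 0.05-0.95 band
    after burn-in are flagged with a warning, not dropped.
    """
    k = _check_panels(panels)
    if hpriors.k != k:
        raise InvalidInputError(f"priors have k={hpriors.k} but panels have k={k}")
    B = pattern_matrix(k)
    counts_mat = np.stack([p.counts.counts for p in panels])
    ns = counts_mat.sum(axis=1)
    region_ids = [p.region_id for p in panels]

    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seed(config.seed, c))
        draws, theta_tuner, tau_tuner = _hier_chain(
            counts_mat, ns, B, hpriors, config, rng
        )
        for label, tuner in (("theta", theta_tuner), ("tau", tau_tuner)):
            rate = tuner.acceptance_rate
            if np.isfinite(rate) and not 0.05 <= rate <= 0.95:
                warnings.warn(
                    f"chain {c}: post-burn-in {label} acceptance rate {rate:.2f} "
                    "outside [0.05, 0.95]; inspect convergence diagnostics",
                    UserWarning, stacklevel=2,
                )
        chains.append(draws)

    names = param_names(k, region_ids=region_ids) + ["mu", "tau"]
    return PosteriorDraws(names=names, draws=np.stack(chains), config=config)


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

def compare_fits(separate: dict, hierarchical: PosteriorDraws,
                 level: float = 0.95) -> pd.DataFrame:
    """Per-region comparison of separate and hierarchical prevalence posteriors.

    One row per region: posterior mean, equal-tailed interval and its width
    under each design, plus the shrinkage distance (how far the hierarchical
    mean moved from the separate mean toward the grand mean).  Raises if the
    two fits do not cover the same regions.
    """
    hier_regions = {n[3:] for n in hierarchical.names if n.startswith("pi_")}
    if set(separate) != hier_regions:
        raise InvalidInputError(
            f"region mismatch: separate={sorted(separate)} hierarchical={sorted(hier_regions)}"
        )
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for region in sorted(separate):
        sep = separate[region].pooled("pi")
        hier = hierarchical.pooled(f"pi_{region}")
        sep_lo, sep_hi = np.quantile(sep, [lo_q, hi_q])
        hier_lo, hier_hi = np.quantile(hier, [lo_q, hi_q])
        rows.append({
            "region": region,
            "separate_mean": sep.mean(),
            "separate_lower": sep_lo,
            "separate_upper": sep_hi,
            "separate_width": sep_hi - sep_lo,
            "hierarchical_mean": hier.mean(),
            "hierarchical_lower": hier_lo,
            "hierarchical_upper": hier_hi,
            "hierarchical_width": hier_hi - hier_lo,
            "shrinkage": abs(hier.mean() - sep.mean()),
        })
    return pd.DataFrame(rows).set_index("region")
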