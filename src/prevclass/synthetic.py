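"""Synthetic test panels with the exact structure the models assume.

The generator plays the role of the administrative-database population:
each individual's true disease status is Bernoulli(pi); given status, the
k binary tests fire independently, a true case turning positive on test j
with probability S_j and a non-case with probability 1 - C_j.  Tabulating
the resulting outcome patterns yields the cross-classified counts every
estimator in this package consumes, so the whole pipeline is testable
without registry data.

Sub-stream seeding is deterministic: replicate/region `i` of master seed
`s` uses ``numpy.random.SeedSequence([s, i])`` (see
:func:`prevclass.samplers.chain_seed`), so panels are reproducible across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core import InvalidInputError, MisclassParams, TestPanelCounts, pattern_matrix
from .samplers import cell_probabilities, chain_seed


@dataclass(frozen=True)
class SimulationSpec:
    """True parameters, sample size and seed for one simulated panel."""

    params: MisclassParams
    n: int
    seed: int

    def __post_init__(self):
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise InvalidInputError(f"n must be a positive integer, got {self.n!r}")


def simulate_panel(spec: SimulationSpec) -> TestPanelCounts:
    """Individual-level simulation of a k-test panel.

    Draws n true statuses, then each test result conditionally independently
    given status, and tabulates patterns in the fixed index order (test 1 =
    most significant bit, 1 = positive).
    """
    params, n = spec.params, spec.n
    k = params.k
    rng = np.random.default_rng(chain_seed(spec.seed, 0))
    status = rng.random(n) < params.pi
    p_pos = np.where(status[:, None], params.S[None, :], 1.0 - params.C[None, :])
    results = rng.random((n, k)) < p_pos
    weights = 1 << (k - 1 - np.arange(k))
    idx = results @ weights
    counts = np.bincount(idx, minlength=2 ** k)
    return TestPanelCounts(k=k, counts=counts)


def simulate_panel_multinomial(spec: SimulationSpec) -> TestPanelCounts:
    """Fast shortcut: one multinomial draw over the 2**k pattern probabilities.

    Distributionally equivalent to :func:`simulate_panel` (the individual
    pattern assignments are exchangeable); uses a different stream of the
    same seed, so the two functions give different but equally valid panels.
    """
    probs = cell_probabilities(spec.params)
    rng = np.random.default_rng(chain_seed(spec.seed, 1))
    counts = rng.multinomial(spec.n, probs)
    return TestPanelCounts(k=spec.params.k, counts=counts)


def simulate_regions(hypermean: float, hyperspread: float, S, C,
                     n_per_region, seed: int, return_truth: bool = False):
    """Multi-region panels with logit-normal heterogeneity in prevalence.

    Region prevalences are drawn as ``expit(Normal(hypermean, hyperspread))``
    on the logit scale; sensitivities and specificities are shared across
    regions (the tests are the same database fields everywhere).  Region ids
    are ``region_01, region_02, ...`` in input order.

    Returns a list of :class:`~prevclass.hierarchical.RegionPanel`; with
    `return_truth` also the vector of drawn true prevalences.
    """
    from .hierarchical import RegionPanel  # deferred: avoids import cycle

    S = np.atleast_1d(np.asarray(S, dtype=float))
    C = np.atleast_1d(np.asarray(C, dtype=float))
    n_per_region = np.atleast_1d(np.asarray(n_per_region))
    if len(S) != len(C):
        raise InvalidInputError("S and C must have equal length")
    if hyperspread < 0:
        raise InvalidInputError(f"hyperspread must be >= 0, got {hyperspread}")
    if n_per_region.ndim != 1 or len(n_per_region) < 1 or np.any(n_per_region < 1):
        raise InvalidInputError("n_per_region must be a vector of positive sizes")

    n_regions = len(n_per_region)
    rng = np.random.default_rng(chain_seed(seed, 0))
    pis = expit(hypermean + hyperspread * rng.standard_normal(n_regions))
    panels = []
    for r in range(n_regions):
        params = MisclassParams(pi=float(pis[r]), S=S, C=C)
        sub_seed = int(chain_seed(seed, r + 1).generate_state(1)[0] % (2 ** 31))
        counts = simulate_panel(SimulationSpec(params=params, n=int(n_per_region[r]),
                                               seed=sub_seed))
        panels.append(RegionPanel(region_id=f"region_{r + 1:02d}", counts=counts))
    if return_truth:
        return panels, pis
    return panels
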