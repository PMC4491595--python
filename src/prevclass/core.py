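"""Closed-form misclassification algebra for prevalence estimation.

An imperfect binary diagnostic "test" (a claims code, a prescription flag,
a procedure code ...) observes true disease status with sensitivity ``S``
(probability a true case is flagged) and specificity ``C`` (probability a
non-case is not flagged).  The apparent prevalence ``P`` — the fraction of
the population flagged positive — mixes true and false positives:

    P = pi * S + (1 - pi) * (1 - C)

where ``pi`` is the true prevalence.  Inverting gives the Rogan–Gladen
correction

    pi = (P + C - 1) / (S + C - 1),

defined whenever the test is informative (``S + C > 1``).

This module also does the parameter/degrees-of-freedom accounting that
decides whether a k-test latent class model is identifiable from its
2**k cross-classified table alone: ``2k + 1`` parameters against
``2**k - 1`` degrees of freedom, so three tests is the smallest
identifiable design.

Pattern-index convention (fixed package-wide): the outcome pattern of k
tests is encoded as a k-bit integer with test 1 as the most significant
bit and bit value 1 meaning "positive".  For k = 3 the index order is
000, 001, 010, ..., 111, i.e. index 5 = pattern "101" = tests 1 and 3
positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# Errors and warnings
# ---------------------------------------------------------------------------

class InvalidInputError(ValueError):
    """An argument violates its domain (probability outside [0, 1], k < 1, ...)."""


class DegenerateTestError(ValueError):
    """The test is uninformative (S + C <= 1): the correction is undefined."""


class WrongModelError(ValueError):
    """The data shape does not match the requested model (e.g. k != 1)."""


class FeasibilityWarning(UserWarning):
    """Observed proportion fell outside the feasible band [1 - C, S]; result clamped."""


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0.0 or value > 1.0:
        raise InvalidInputError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


# ---------------------------------------------------------------------------
# Pattern-index helpers
# ---------------------------------------------------------------------------

def pattern_matrix(k: int) -> np.ndarray:
    """(2**k, k) 0/1 matrix; row i column j is the result of test j+1 in pattern i.

    Test 1 occupies the most significant bit, 1 = positive.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise InvalidInputError(f"k must be an integer >= 1, got {k!r}")
    idx = np.arange(2 ** k)
    shifts = k - 1 - np.arange(k)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int64)


def pattern_string(index: int, k: int) -> str:
    """Render a pattern index as a k-character 0/1 string, test 1 leftmost."""
    if not 0 <= index < 2 ** k:
        raise InvalidInputError(f"pattern index {index} out of range for k={k}")
    return format(index, f"0{k}b")


def pattern_index(pattern: str) -> int:
    """Parse a 0/1 string (test 1 leftmost) into the pattern index."""
    if not pattern or any(ch not in "01" for ch in pattern):
        raise InvalidInputError(f"pattern must be a non-empty 0/1 string, got {pattern!r}")
    return int(pattern, 2)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MisclassParams:
    """True prevalence plus per-test sensitivity and specificity.

    Parameters
    ----------
    pi : float
        True prevalence, in [0, 1].
    S : array-like of float
        Sensitivity of each of the k tests.
    C : array-like of float
        Specificity of each of the k tests; must have the same length as `S`.
    """

    pi: float
    S: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "S", np.atleast_1d(np.asarray(self.S, dtype=float)))
        object.__setattr__(self, "C", np.atleast_1d(np.asarray(self.C, dtype=float)))
        _check_prob(self.pi, "pi")
        if self.S.ndim != 1 or self.C.ndim != 1 or len(self.S) != len(self.C):
            raise InvalidInputError("S and C must be 1-d vectors of equal length")
        if len(self.S) < 1:
            raise InvalidInputError("at least one test is required (k >= 1)")
        for j, (s, c) in enumerate(zip(self.S, self.C), start=1):
            _check_prob(s, f"S[{j}]")
            _check_prob(c, f"C[{j}]")

    @property
    def k(self) -> int:
        return len(self.S)


@dataclass(frozen=True)
class TestPanelCounts:
    """Cross-classified counts of k binary test results.

    ``counts[i]`` is the number of individuals whose outcome pattern has
    index ``i`` under the fixed convention (test 1 = most significant bit,
    1 = positive).  ``n`` is the total sample size.
    """

    __test__ = False  # not a test class, despite the name

    k: int
    counts: np.ndarray
    n: int = field(init=False)

    def __post_init__(self):
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise InvalidInputError(f"k must be an integer >= 1, got {self.k!r}")
        counts = np.asarray(self.counts)
        if counts.shape != (2 ** self.k,):
            raise InvalidInputError(
                f"counts must have length 2**k = {2 ** self.k}, got shape {counts.shape}"
            )
        if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
            raise InvalidInputError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "n", int(self.counts.sum()))

    @classmethod
    def from_positives(cls, positives: int, n: int) -> "TestPanelCounts":
        """Single-test (k=1) panel from a positives/total pair."""
        if not (0 <= positives <= n):
            raise InvalidInputError(f"need 0 <= positives <= n, got {positives}/{n}")
        return cls(k=1, counts=np.array([n - positives, positives]))

    @property
    def apparent_prevalence_hat(self) -> float:
        """Observed positive proportion; defined for k = 1 only."""
        if self.k != 1:
            raise WrongModelError("apparent prevalence is defined for k = 1 panels")
        if self.n == 0:
            raise InvalidInputError("empty panel has no apparent prevalence")
        return self.counts[1] / self.n


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Parameter count versus data degrees of freedom for a k-test design."""

    k: int
    n_params: int
    n_df: int
    identifiable: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apparent_prevalence(pi: float, S: float, C: float) -> float:
    """Forward misclassification relation P = pi*S + (1 - pi)*(1 - C).

    With no true cases positives arise only as false positives (rate 1 - C);
    with prevalence one the positive rate equals the sensitivity S.
    """
    pi = _check_prob(pi, "pi")
    S = _check_prob(S, "S")
    C = _check_prob(C, "C")
    return pi * S + (1.0 - pi) * (1.0 - C)


def correct_prevalence(P: float, S: float, C: float) -> float:
    """Rogan–Gladen correction pi = (P + C - 1) / (S + C - 1).

    Requires an informative test, ``S + C > 1``.  The observed proportion can
    fall outside the feasible band ``[1 - C, S]`` by sampling noise, in which
    case the raw value lies outside [0, 1]; it is clamped and a
    :class:`FeasibilityWarning` is emitted.  When ``S = C = 1`` the correction
    reduces to ``P`` itself.
    """
    P = _check_prob(P, "P")
    S = _check_prob(S, "S")
    C = _check_prob(C, "C")
    denom = S + C - 1.0
    if denom <= 0.0:
        raise DegenerateTestError(
            f"uninformative test: S + C = {S + C:.6g} <= 1, correction undefined"
        )
    raw = (P + C - 1.0) / denom
    if raw < 0.0 or raw > 1.0:
        warnings.warn(
            f"observed P={P:.6g} outside feasible band [{1 - C:.6g}, {S:.6g}]; "
            f"corrected prevalence clamped from {raw:.6g} to [0, 1]",
            FeasibilityWarning,
            stacklevel=2,
        )
    return float(min(1.0, max(0.0, raw)))


def identifiability(k: int) -> IdentifiabilityReport:
    """Count parameters (2k + 1) against degrees of freedom (2**k - 1).

    A k-test conditional-independence latent class model has a sensitivity
    and a specificity per test plus the prevalence; the cross-classified
    table supplies ``2**k - 1`` free cell proportions.  The design is
    identifiable from the data alone iff the degrees of freedom cover the
    parameters, which first happens at k = 3 (7 vs 7).
    """
    if not (isinstance(k, (int, np.integer)) and not isinstance(k, bool) and k >= 1):
        raise InvalidInputError(f"k must be an integer >= 1, got {k!r}")
    n_params = 2 * int(k) + 1
    n_df = 2 ** int(k) - 1
    return IdentifiabilityReport(
        k=int(k), n_params=n_params, n_df=n_df, identifiable=n_df >= n_params
    )
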