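"""File I/O, posterior summaries and convergence diagnostics.

Counts-file dialects (fixed, no variants):

* CSV — columns ``test_1 .. test_k`` with 0/1 entries plus ``count``; an
  optional leading ``region`` column turns the file into a multi-region
  collection.  Rows may appear in any order; missing patterns are read as
  zero with a warning (sparse tables are expected at small n).
* JSON — an object mapping 0/1 pattern strings (test 1 leftmost) to
  counts, e.g. ``{"111": 10, "000": 90}``; or ``{"regions": {"A": {...},
  ...}}`` for a collection.

Posterior draws round-trip through a long-format CSV with ``chain`` and
``iteration`` columns.  Summaries report, per parameter, the posterior
mean, median, sd, equal-tailed credible interval, the Gelman–Rubin
potential scale reduction factor (between/within chain variance; needs
at least two chains) and an effective sample size from the autocorrelation
series truncated at the first negative pair sum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InvalidInputError, TestPanelCounts, pattern_index, pattern_string
from .hierarchical import RegionPanel
from .samplers import McmcConfig, PosteriorDraws


# ---------------------------------------------------------------------------
# Counts I/O
# ---------------------------------------------------------------------------

def _infer_format(path, fmt):
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise InvalidInputError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise InvalidInputError(f"cannot infer format from {path!r}; pass format=")


def _counts_from_mapping(mapping: dict, source: str) -> TestPanelCounts:
    if not mapping:
        raise InvalidInputError(f"{source}: no patterns found")
    lengths = {len(p) for p in mapping}
    if len(lengths) != 1:
        raise InvalidInputError(f"{source}: inconsistent pattern lengths {sorted(lengths)}")
    k = lengths.pop()
    counts = np.zeros(2 ** k, dtype=np.int64)
    for pat, c in mapping.items():
        if float(c) != int(c) or int(c) < 0:
            raise InvalidInputError(f"{source}: count for pattern {pat!r} must be a "
                                    f"non-negative integer, got {c!r}")
        counts[pattern_index(pat)] = int(c)
    if len(mapping) < 2 ** k:
        missing = 2 ** k - len(mapping)
        warnings.warn(f"{source}: {missing} of {2 ** k} patterns absent; filled as zero",
                      UserWarning, stacklevel=3)
    return TestPanelCounts(k=k, counts=counts)


def _frame_to_mapping(frame: pd.DataFrame, source: str) -> dict:
    test_cols = sorted(
        (c for c in frame.columns if c.startswith("test_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not test_cols or "count" not in frame.columns:
        raise InvalidInputError(f"{source}: need columns test_1..test_k and count")
    expected = [f"test_{j}" for j in range(1, len(test_cols) + 1)]
    if test_cols != expected:
        raise InvalidInputError(f"{source}: test columns {test_cols} are not contiguous "
                                f"test_1..test_{len(test_cols)}")
    vals = frame[test_cols].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise InvalidInputError(f"{source}: test columns must contain only 0/1")
    patterns = ["".join(str(int(v)) for v in row) for row in vals]
    if len(set(patterns)) != len(patterns):
        raise InvalidInputError(f"{source}: duplicate pattern rows")
    return dict(zip(patterns, frame["count"].tolist()))


def read_counts(path, format: str | None = None):
    """Read a counts table; returns TestPanelCounts or a list of RegionPanel.

    Missing patterns are filled as zero with a warning; negative,
    non-integer or inconsistently-sized patterns raise
    :class:`~prevclass.core.InvalidInputError`.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "json":
        payload = json.loads(path.read_text())
        if not isinstance(payload, dict):
            raise InvalidInputError(f"{path}: JSON counts must be an object")
        if "regions" in payload:
            panels = [
                RegionPanel(region_id=str(rid),
                            counts=_counts_from_mapping(m, f"{path}[{rid}]"))
                for rid, m in payload["regions"].items()
            ]
            ks = {p.counts.k for p in panels}
            if len(ks) > 1:
                raise InvalidInputError(f"{path}: regions disagree on k: {sorted(ks)}")
            return panels
        return _counts_from_mapping(payload, str(path))

    frame = pd.read_csv(path)
    if "region" in frame.columns:
        panels = [
            RegionPanel(region_id=str(rid),
                        counts=_counts_from_mapping(
                            _frame_to_mapping(group.drop(columns="region"),
                                              f"{path}[{rid}]"),
                            f"{path}[{rid}]"))
            for rid, group in frame.groupby("region", sort=False)
        ]
        ks = {p.counts.k for p in panels}
        if len(ks) > 1:
            raise InvalidInputError(f"{path}: regions disagree on k: {sorted(ks)}")
        return panels
    return _counts_from_mapping(_frame_to_mapping(frame, str(path)), str(path))


def write_counts(path, data, format: str | None = None) -> None:
    """Write TestPanelCounts or a list of RegionPanel in the package dialect."""
    fmt = _infer_format(path, format)
    path = Path(path)
    panels = data if isinstance(data, list) else None
    if fmt == "json":
        if panels is not None:
            payload = {"regions": {
                p.region_id: {pattern_string(i, p.counts.k): int(c)
                              for i, c in enumerate(p.counts.counts)}
                for p in panels
            }}
        else:
            payload = {pattern_string(i, data.k): int(c)
                       for i, c in enumerate(data.counts)}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return

    def rows_for(counts: TestPanelCounts, region=None):
        for i, c in enumerate(counts.counts):
            row = {} if region is None else {"region": region}
            for j in range(counts.k):
                row[f"test_{j + 1}"] = int(pattern_string(i, counts.k)[j])
            row["count"] = int(c)
            yield row

    if panels is not None:
        frame = pd.DataFrame(
            r for p in panels for r in rows_for(p.counts, region=p.region_id)
        )
    else:
        frame = pd.DataFrame(rows_for(data))
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Draws I/O
# ---------------------------------------------------------------------------

def write_draws(path, draws: PosteriorDraws) -> None:
    """Write posterior draws as long-format CSV (chain, iteration, parameters)."""
    draws.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_draws(path, config: McmcConfig | None = None) -> PosteriorDraws:
    """Read draws written by :func:`write_draws`.

    The original sampler settings are not stored in the CSV; a surrogate
    config reflecting the stored shape is attached unless one is supplied.
    """
    frame = pd.read_csv(path)
    names = [c for c in frame.columns if c not in ("chain", "iteration")]
    n_chains = frame["chain"].nunique()
    n_iter = frame["iteration"].nunique()
    arr = (frame.sort_values(["chain", "iteration"])[names]
           .to_numpy().reshape(n_chains, n_iter, len(names)))
    if config is None:
        config = McmcConfig(seed=0, n_iter=n_iter, burn_in=0, n_chains=n_chains)
    return PosteriorDraws(names=names, draws=arr, config=config)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from m chains of length n.

    sqrt(V/W) with V = (n-1)/n * W + B/n, W the mean within-chain variance
    and B the between-chain variance of chain means (times n).  Returns NaN
    for a single chain (the statistic needs between-chain information) and
    1.0 for degenerate constant draws.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 2:
        return float("nan")
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    V = (n - 1) / n * W + B / n
    return float(np.sqrt(V / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence.

    Autocorrelations are averaged across chains against the pooled variance
    and summed in adjacent pairs; the sum is truncated at the first pair
    with a negative total.  Capped at the total number of retained draws.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    total = m * n
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return float(total)
    B = n * chains.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n

    centered = chains - chains.mean(axis=1, keepdims=True)
    max_lag = n - 1
    # mean autocovariance across chains at each lag, via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    freq = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(freq * np.conj(freq), nfft, axis=1)[:, : n].real / n
    acov = acov.mean(axis=0)
    rho = 1.0 - (W - acov) / var_plus
    rho[0] = 1.0

    tau = 1.0
    lag = 1
    while lag + 1 <= max_lag:
        pair = rho[lag] + rho[lag + 1]
        if pair < 0.0:
            break
        tau += 2.0 * pair
        lag += 2
    return float(min(total, total / tau))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior summary table with convergence diagnostics."""

    table: pd.DataFrame
    level: float

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6g")

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.6g}")


def summarize(draws: PosteriorDraws, level: float = 0.95) -> PosteriorSummary:
    """Posterior mean, median, sd, equal-tailed interval, R-hat and ESS per parameter.

    With a single chain R-hat is reported as NaN (unavailable), never
    fabricated.  Requires at least two retained draws.
    """
    if not 0.0 < level < 1.0:
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    if draws.n_kept * draws.n_chains < 2:
        raise InvalidInputError("need at least two retained draws to summarize")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name in draws.names:
        chains = draws.param(name)
        pooled = chains.reshape(-1)
        lo, hi = np.quantile(pooled, [lo_q, hi_q])
        rows.append({
            "parameter": name,
            "mean": pooled.mean(),
            "median": float(np.median(pooled)),
            "sd": pooled.std(ddof=1) if pooled.size > 1 else 0.0,
            "lower": lo,
            "upper": hi,
            "rhat": gelman_rubin(chains),
            "ess": effective_sample_size(chains),
        })
    return PosteriorSummary(table=pd.DataFrame(rows).set_index("parameter"),
                            level=level)
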