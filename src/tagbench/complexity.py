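"""Library complexity estimation and ratio-based downsampling.

The number of distinct molecules in a sequencing library is estimated from
the duplication histogram under a zero-truncated Poisson sampling model:
each of N unique molecules is read Poisson(lambda) times and unobserved
molecules are truncated away, so the total read count R and observed unique
count u are coupled through

    R / u = lambda / (1 - exp(-lambda)).

Solving this monotone relation for lambda gives the per-molecule depth and
N_hat = R / lambda.  Libraries are then equalized to a common complexity by
Bernoulli thinning of reads at p = target_unique / N_hat followed by
deduplication, mirroring per-read random subsampling with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .fragments import FragmentLibrary


@dataclass(frozen=True)
class DupHistogram:
    """Mapping j -> number of molecules observed exactly j times (j >= 1)."""

    counts: dict[int, int]

    def __post_init__(self):
        if any(j < 1 or c < 0 for j, c in self.counts.items()):
            raise ValueError("histogram requires j >= 1 and counts >= 0")

    @property
    def total_reads(self) -> int:
        return sum(j * c for j, c in self.counts.items())

    @property
    def observed_unique(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ComplexityEstimate:
    library_id: str
    total_reads: int
    observed_unique: int
    estimated_unique: float
    proportion_unique: float
    lambda_hat: float
    status: str = "ok"  # "ok" | "no_duplicates"


def dup_histogram(lib: FragmentLibrary) -> DupHistogram:
    """Tally the duplication histogram of a (non-deduplicated) library."""
    vals, counts = np.unique(lib.frame["copy_count"].to_numpy(), return_counts=True)
    return DupHistogram({int(j): int(c) for j, c in zip(vals, counts)})


def ztp_lambda(ratio: float, rtol: float = 1e-12) -> float:
    """Solve lambda / (1 - exp(-lambda)) = ratio for lambda (ratio > 1)."""
    if ratio <= 1.0:
        raise ValueError("reads-per-unique ratio must exceed 1")
    f = lambda lam: lam / -np.expm1(-lam) - ratio
    lo = 1e-12
    hi = ratio + 1.0  # g(lambda) > lambda, so the root is below ratio
    return float(brentq(f, lo, hi, rtol=rtol, maxiter=200))


def estimate_unique(hist: DupHistogram, library_id: str = "lib") -> ComplexityEstimate:
    """Zero-truncated Poisson maximum-likelihood unique-molecule estimate.

    If no duplicates are observed (R == u) the estimator is unbounded; the
    observed unique count is returned with status ``"no_duplicates"``.
    """
    R = hist.total_reads
    u = hist.observed_unique
    if u < 1:
        raise ValueError("histogram has no observed molecules")
    if R < u:
        raise ValueError(f"total reads {R} below observed unique {u}")
    if R == u:
        return ComplexityEstimate(library_id, R, u, float(u), 1.0, 0.0, "no_duplicates")
    lam = ztp_lambda(R / u)
    n_hat = max(R / lam, float(u))  # estimator never below observed unique
    return ComplexityEstimate(library_id, R, u, n_hat, n_hat / R, lam)


def estimate_library(lib: FragmentLibrary) -> ComplexityEstimate:
    return estimate_unique(dup_histogram(lib), library_id=lib.library_id)


def downsample(
    lib: FragmentLibrary,
    target_unique: float,
    estimate: ComplexityEstimate,
    seed: int = 1,
) -> FragmentLibrary:
    """Thin reads at p = target_unique / estimated_unique (per-read Bernoulli).

    Returns a non-deduplicated library; molecules losing all reads drop out.
    """
    if lib.deduplicated:
        raise ValueError("downsample expects a non-deduplicated library")
    p = target_unique / estimate.estimated_unique
    if p > 1.0 + 1e-12:
        raise ValueError(
            f"target_unique {target_unique} exceeds estimated unique "
            f"{estimate.estimated_unique:.0f}; skip downsampling for the"
            " limiting library"
        )
    p = min(p, 1.0)
    if p == 1.0:
        return lib
    rng = np.random.default_rng(seed)
    kept = rng.binomial(lib.frame["copy_count"].to_numpy(), p)
    frame = lib.frame.assign(copy_count=kept)
    frame = frame[frame["copy_count"] > 0]
    return lib.replace(frame, deduplicated=False)


def deduplicate(lib: FragmentLibrary) -> FragmentLibrary:
    """Collapse to one record per distinct fragment coordinate pair."""
    if lib.deduplicated:
        return lib
    frame = lib.frame.assign(copy_count=1)
    return lib.replace(frame, deduplicated=True)


def filter_min_unique(
    libs: Sequence[FragmentLibrary], min_unique: int
) -> list[FragmentLibrary]:
    """Retain libraries with observed unique count >= min_unique (inclusive)."""
    return [lib for lib in libs if lib.n_unique >= min_unique]


def normalize_complexity(
    libs: Sequence[FragmentLibrary],
    target_unique: float | None = None,
    seed: int = 1,
) -> list[FragmentLibrary]:
    """Downsample every library to a common estimated complexity, then dedup.

    With ``target_unique=None`` the limiting (lowest) estimated unique count
    across the libraries is used; the limiting library itself is thinned at
    p = 1 (identity).
    """
    estimates = [estimate_library(lib) for lib in libs]
    if target_unique is None:
        target_unique = min(e.estimated_unique for e in estimates)
    out = []
    for lib, est in zip(libs, estimates):
        thinned = downsample(lib, target_unique, est, seed=seed)
        out.append(deduplicate(thinned))
    return out


def complexity_report(libs: Iterable[FragmentLibrary]) -> pd.DataFrame:
    """Per-library complexity table (TSV-ready)."""
    rows = []
    for lib in libs:
        est = estimate_library(lib)
        rows.append(
            {
                "library_id": est.library_id,
                "total_reads": est.total_reads,
                "observed_unique": est.observed_unique,
                "estimated_unique": est.estimated_unique,
                "proportion_unique": est.proportion_unique,
                "lambda_hat": est.lambda_hat,
            }
        )
    return pd.DataFrame(rows)
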