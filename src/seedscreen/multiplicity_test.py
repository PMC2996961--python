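"""Sampling-based significance test for repeated seeds among top hits.

Seeing the same seed on several of the top-k siRNAs of a screen hints at
seed-driven off-target selection.  Whether that multiplicity is
surprising depends on the seed composition of the whole library (popular
seeds collide by chance, a birthday problem).  The test draws many
random samples of k siRNAs from the library, records a multiplicity
statistic of their seeds, and reports an add-one empirical p-value for
the observed value.

Statistics:

- ``n_repeated``: number of distinct seeds occurring >= 2 times;
- ``max_count``: largest number of siRNAs sharing one seed;
- ``n_with_count_ge_m``: number of distinct seeds occurring >= m times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MultiplicityNull", "EmpiricalP", "sample_null", "empirical_p", "STATISTICS"]


def _stat_from_counts(counts: np.ndarray, statistic: str, m: int) -> int:
    if statistic == "n_repeated":
        return int((counts >= 2).sum())
    if statistic == "max_count":
        return int(counts.max())
    if statistic == "n_with_count_ge_m":
        return int((counts >= m).sum())
    raise ValueError(f"unknown statistic {statistic!r}")


STATISTICS = ("n_repeated", "max_count", "n_with_count_ge_m")


@dataclass
class MultiplicityNull:
    """Null distribution of a seed-multiplicity statistic for samples of k."""

    statistic: str
    k: int
    n_iter: int
    rng_seed: int
    m: int
    samples: np.ndarray  # shape (n_iter,), integer statistic values

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if len(self.samples) != self.n_iter:
            raise ValueError("samples length must equal n_iter")
        if (self.samples < 0).any():
            raise ValueError("statistic samples must be non-negative")


def sample_null(
    library_seeds: Sequence[str],
    k: int = 20,
    n_iter: int = 5000,
    statistic: str = "n_repeated",
    rng_seed: int = 0,
    m: int = 2,
    replace: bool = False,
) -> MultiplicityNull:
    """Monte Carlo null for seed multiplicity among k randomly drawn siRNAs.

    Each iteration samples k siRNAs from the library (without
    replacement by default, preserving the library's seed frequencies)
    and records the statistic of their seeds.  Bit-reproducible for a
    fixed ``rng_seed``.
    """
    seeds = np.asarray(library_seeds)
    n = len(seeds)
    if k <= 0:
        raise ValueError("k must be positive")
    if not replace and k > n:
        raise ValueError(f"k={k} exceeds library size {n}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")

    # integer-code the seeds once; multiplicity only needs equality
    _, codes = np.unique(seeds, return_inverse=True)
    rng = np.random.default_rng(rng_seed)
    out = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        idx = rng.choice(n, size=k, replace=replace)
        counts = np.bincount(codes[idx])
        out[i] = _stat_from_counts(counts[counts > 0], statistic, m)
    return MultiplicityNull(
        statistic=statistic, k=k, n_iter=n_iter, rng_seed=rng_seed, m=m, samples=out
    )


@dataclass(frozen=True)
class EmpiricalP:
    """Add-one empirical p-value with its reporting convention."""

    observed: int
    p: float
    n_iter: int
    n_as_extreme: int
    convention: str  # e.g. "P = 0.0134" or "P < 0.0002"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.convention


def empirical_p(null: MultiplicityNull, observed: int) -> EmpiricalP:
    """p = (#samples >= observed + 1) / (n_iter + 1).

    The add-one correction counts the observed value itself as one
    sample, so p can never be exactly zero.  When no null sample reaches
    the observed value the conventional report is the strict bound
    "P < 1/n_iter" (e.g. "P < 0.0002" at 5,000 iterations).
    """
    if observed < 0:
        raise ValueError("observed statistic must be >= 0")
    if null.n_iter == 0 or len(null.samples) == 0:
        raise ValueError("empty null distribution")
    count = int((null.samples >= observed).sum())
    p = (count + 1) / (null.n_iter + 1)
    if count == 0:
        convention = f"P < {1.0 / null.n_iter:g}"
    else:
        convention = f"P = {count / null.n_iter:.4g}"
    return EmpiricalP(
        observed=observed, p=p, n_iter=null.n_iter, n_as_extreme=count,
        convention=convention,
    )
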