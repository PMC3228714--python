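"""Richness and diversity statistics on OTU abundance vectors.

Implements the bias-corrected Chao1 richness estimator with a log-normal
95% confidence interval on the unseen-species count, the Shannon index
(natural log), a subsample-normalized Shannon index (mean over repeated
subsamples without replacement, to compare samples of unequal depth) and
the analytic hypergeometric rarefaction curve.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import InvariantError

__all__ = [
    "AbundanceVector",
    "Chao1Estimate",
    "chao1",
    "shannon",
    "normalized_shannon",
    "rarefaction_curve",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AbundanceVector:
    """Per-OTU read counts (each >= 1) with the derived richness symbols."""

    counts: tuple[int, ...]

    def __init__(self, counts: Sequence[int]):
        counts = tuple(int(c) for c in counts)
        if any(c < 1 for c in counts):
            raise InvariantError("abundance counts must all be >= 1")
        object.__setattr__(self, "counts", counts)

    @property
    def sobs(self) -> int:
        """Observed OTU richness."""
        return len(self.counts)

    @property
    def n1(self) -> int:
        """Singleton count."""
        return sum(1 for c in self.counts if c == 1)

    @property
    def n2(self) -> int:
        """Doubleton count."""
        return sum(1 for c in self.counts if c == 2)

    @property
    def n(self) -> int:
        """Total reads."""
        return sum(self.counts)


@dataclass(frozen=True)
class Chao1Estimate:
    estimate: float
    lci95: float
    hci95: float

    def __post_init__(self) -> None:
        if not self.lci95 <= self.estimate <= self.hci95:
            raise InvariantError("Chao1 CI does not bracket the estimate")


def chao1(v: AbundanceVector) -> Chao1Estimate:
    """Bias-corrected Chao1 richness estimate with a 95% CI.

    estimate = Sobs + n1(n1-1) / (2(n2+1)).

    The CI is the log-normal construction on T = estimate - Sobs (the
    estimated number of unseen OTUs), using the classic variance of the
    bias-corrected estimator; with no singletons there is no evidence of
    unseen OTUs and the CI collapses to (Sobs, Sobs).
    """
    if not v.counts:
        raise ValueError("empty abundance vector")
    sobs, f1, f2 = float(v.sobs), float(v.n1), float(v.n2)
    est = sobs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    t = est - sobs
    if f1 == 0.0 or t <= 0.0:
        return Chao1Estimate(estimate=est, lci95=est, hci95=est)
    if f2 > 0.0:
        var = (
            f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
            + f1 * (2.0 * f1 - 1.0) ** 2 / (4.0 * (f2 + 1.0) ** 2)
            + f1**2 * f2 * (f1 - 1.0) ** 2 / (4.0 * (f2 + 1.0) ** 4)
        )
    else:
        var = (
            f1 * (f1 - 1.0) / 2.0
            + f1 * (2.0 * f1 - 1.0) ** 2 / 4.0
            - f1**4 / (4.0 * est)
        )
    k = np.exp(Z95 * np.sqrt(np.log1p(var / t**2)))
    return Chao1Estimate(estimate=est, lci95=sobs + t / k, hci95=sobs + t * k)


def shannon(v: AbundanceVector) -> float:
    """Shannon diversity H' = -sum p_i ln p_i (natural log)."""
    if not v.counts:
        raise ValueError("empty abundance vector")
    c = np.asarray(v.counts, dtype=float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def normalized_shannon(
    labels: Sequence[str],
    size: int,
    reps: int = 100,
    seed: int = 0,
) -> float:
    """Mean Shannon index over repeated subsamples without replacement.

    ``labels`` gives each read's OTU; ``size`` reads are drawn uniformly
    without replacement ``reps`` times (default 100) and the Shannon index
    of each induced abundance vector is averaged.  Each replicate uses its
    own spawned RNG stream, so the result is deterministic given ``seed``.
    """
    labels = np.asarray(labels, dtype=object)
    total = len(labels)
    if size > total:
        raise ValueError(f"subsample size {size} exceeds total reads {total}")
    if size < 1 or reps < 1:
        raise ValueError("size and reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(reps)
    values = np.empty(reps)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        idx = rng.choice(total, size=size, replace=False)
        _, counts = np.unique(labels[idx], return_counts=True)
        values[r] = shannon(AbundanceVector(counts))
    return float(values.mean())


def rarefaction_curve(
    v: AbundanceVector, depths: Sequence[int]
) -> list[tuple[int, float]]:
    """Analytic rarefaction: expected OTU count at each subsample depth.

    E[S(m)] = Sobs - sum_i C(N - c_i, m) / C(N, m), evaluated in log
    space for numerical stability; exact at m = N (gives Sobs) and m = 1
    (gives 1).
    """
    if not v.counts:
        raise ValueError("empty abundance vector")
    n = v.n
    counts = np.asarray(v.counts, dtype=float)
    out = []
    for m in depths:
        m = int(m)
        if not 0 < m <= n:
            raise ValueError(f"depth {m} outside [1, {n}]")
        rest = n - counts
        with np.errstate(invalid="ignore"):
            log_frac = (
                gammaln(rest + 1.0) - gammaln(m * 1.0 + 1.0) - gammaln(rest - m + 1.0)
                - (gammaln(n + 1.0) - gammaln(m * 1.0 + 1.0) - gammaln(n - m + 1.0))
            )
        # OTUs with fewer than m reads left over cannot be entirely missed
        prob_missing = np.where(rest >= m, np.exp(log_frac), 0.0)
        out.append((m, float(v.sobs - prob_missing.sum())))
    return out
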