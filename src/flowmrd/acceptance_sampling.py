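"""Attribute acceptance sampling for negative-case review.

Single-stage attributes plans over a finite lot: given a lot of N reported
negatives, draw n at random for expert re-review and accept the lot when at
most c failures (false negatives) are found. The sample size is chosen so
that, at the stated confidence, acceptance is unlikely whenever the lot's
true-negative proportion falls below the stated quality level. All tail
probabilities are exact hypergeometric sums computed in integer arithmetic —
no binomial or normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

__all__ = [
    "SamplingPlan",
    "LotResult",
    "hypergeom_tail",
    "limiting_defectives",
    "min_sample_size",
    "oc_curve",
    "evaluate_lot",
    "allocate_periodic",
]


def hypergeom_tail(N: int, D: int, n: int, c: int) -> Fraction:
    """Exact P(X <= c) for X ~ Hypergeometric(N, D, n), as a rational."""
    if not 0 <= D <= N or not 0 <= n <= N:
        raise ValueError("need 0 <= D, n <= N")
    total = math.comb(N, n)
    num = sum(math.comb(D, k) * math.comb(N - D, n - k)
              for k in range(0, min(c, D, n) + 1))
    return Fraction(num, total)


def limiting_defectives(N: int, quality: float,
                        convention: str = "strict") -> int:
    """Smallest defective count at which the lot misses the quality level.

    ``strict``: smallest D with (N − D)/N < quality (the literal reading of
    "at least ``quality`` truly negative"). ``ceiling``: D = ceil((1−q)·N).
    Both give D = 23 for N = 444, q = 0.95; they differ at other (N, q).
    """
    if not 0 < quality <= 1:
        raise ValueError("quality must be in (0, 1]")
    if convention == "strict":
        d = next(d for d in range(N + 1) if (N - d) / N < quality)
        return max(d, 1)
    if convention == "ceiling":
        return max(math.ceil((1 - quality) * N), 1)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class SamplingPlan:
    """Single-stage attributes plan over a finite lot.

    ``n_minimal`` is the exact smallest sample size meeting the confidence
    constraint; ``n`` is the operational sample size after rounding up to a
    multiple of the review periods so the workload divides evenly (e.g. 14
    cases per month over a 6-month cycle).
    """

    N: int
    n: int
    c: int
    confidence: float
    quality: float
    d_star: int
    n_minimal: int
    periods: int = 6
    convention: str = "strict"

    def __post_init__(self) -> None:
        if not 0 <= self.c <= self.n <= self.N:
            raise ValueError("need 0 <= c <= n <= N")

    def acceptance_probability(self, defectives: int) -> float:
        return float(hypergeom_tail(self.N, defectives, self.n, self.c))


@dataclass(frozen=True)
class LotResult:
    reviewed: int
    failures: int
    accept: bool
    confirmed_fraction: float  # percent, 1 d.p.


def min_sample_size(N: int, c: int = 1, confidence: float = 0.95,
                    quality: float = 0.95, periods: int = 6,
                    convention: str = "strict") -> SamplingPlan:
    """Derive the attributes plan by exact hypergeometric search.

    Finds the smallest n with P(X <= c | N, d_star, n) <= 1 − confidence by
    summing the exact pmf, then rounds n up to a multiple of ``periods`` for
    even per-period allocation (``periods=1`` disables the rounding). Raises
    if even n = N cannot meet the constraint.
    """
    if N < 1 or c < 0:
        raise ValueError("need N >= 1 and c >= 0")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if periods < 1:
        raise ValueError("periods must be >= 1")
    d_star = limiting_defectives(N, quality, convention)
    beta = Fraction(1) - Fraction(confidence).limit_denominator(10**9)
    n_min = None
    for n in range(c + 1, N + 1):
        if hypergeom_tail(N, d_star, n, c) <= beta:
            n_min = n
            break
    if n_min is None:
        worst = float(hypergeom_tail(N, d_star, N, c))
        raise ValueError(
            f"infeasible plan: even n=N={N} accepts with probability "
            f"{worst:.4g} > {float(beta):.4g}")
    n_op = min(N, periods * math.ceil(n_min / periods))
    return SamplingPlan(N=N, n=n_op, c=c, confidence=confidence,
                        quality=quality, d_star=d_star, n_minimal=n_min,
                        periods=periods, convention=convention)


def oc_curve(plan: SamplingPlan,
             defective_range: Sequence[int]) -> list[float]:
    """Operating-characteristic curve: exact P(accept) per defective count."""
    out = []
    for D in defective_range:
        if D > plan.N:
            raise ValueError(f"defective count {D} exceeds lot size {plan.N}")
        out.append(plan.acceptance_probability(D))
    return out


def evaluate_lot(plan: SamplingPlan, failures: int) -> LotResult:
    """Accept/reject a reviewed lot and report the confirmed-negative fraction."""
    if not 0 <= failures <= plan.n:
        raise ValueError("failures must be between 0 and the sample size")
    confirmed = round(100.0 * (plan.n - failures) / plan.n, 1)
    return LotResult(reviewed=plan.n, failures=failures,
                     accept=failures <= plan.c,
                     confirmed_fraction=confirmed)


def allocate_periodic(n: int, periods: int) -> list[int]:
    """As-even-as-possible integer split of n across periods, larger first."""
    if periods < 1:
        raise ValueError("periods must be >= 1")
    if n < 0:
        raise ValueError("n must be nonnegative")
    base, rem = divmod(n, periods)
    return [base + 1] * rem + [base] * (periods - rem)
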