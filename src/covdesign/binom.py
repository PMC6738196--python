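"""Exact binomial probability mass and tail computations.

Every design quantity in this package — false-positive probabilities of a
variant-calling threshold, detection probabilities at a given allele
fraction, minimum-depth searches — reduces to a binomial tail
P(X >= k) or P(X <= k) with X ~ Binomial(n, p), where ``n`` is the
coverage depth at a genomic position and ``p`` is either a per-base error
rate or a variant allele fraction (VAF).

Tails are computed through the regularized incomplete beta function and
the probability mass through log-gamma, so that depths up to 1e7 neither
overflow nor lose the small tails (~1e-3 and below) that the calling
thresholds sit on.  Normal or Poisson approximations are never used as
decision machinery; :func:`normal_tail_approx` exists only as a labelled
diagnostic cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import special

__all__ = [
    "TrialParams",
    "log_pmf",
    "pmf",
    "cdf",
    "tail_geq",
    "normal_tail_approx",
]


@dataclass(frozen=True)
class TrialParams:
    """Parameters of one binomial sampling situation at a locus.

    Parameters
    ----------
    n
        Coverage depth: number of reads overlapping the position.
    p
        Per-read success probability: the per-base error rate when
        modelling spurious variant reads on wild-type material, or the
        VAF when modelling variant-supporting reads in a mutant sample.
    """

    n: int
    p: float

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int,)) or isinstance(self.n, bool):
            raise TypeError(f"depth n must be an integer, got {self.n!r}")
        if self.n < 1:
            raise ValueError(f"depth n must be >= 1, got {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"probability p must be in [0, 1], got {self.p}")


def _check_k(k: int, n: int, *, upper: int) -> None:
    if not isinstance(k, int) or isinstance(k, bool):
        raise TypeError(f"count k must be an integer, got {k!r}")
    if k < 0 or k > upper:
        raise ValueError(f"count k={k} outside [0, {upper}] for depth n={n}")


def log_pmf(k: int, params: TrialParams) -> float:
    """Log of P(X = k) for X ~ Binomial(n, p), via log-gamma.

    Exact at the degenerate edges: p=0 puts all mass on k=0 and p=1 on
    k=n (log-probability 0.0), every other k having probability zero
    (-inf).
    """
    n, p = params.n, params.p
    _check_k(k, n, upper=n)
    if p == 0.0:
        return 0.0 if k == 0 else -math.inf
    if p == 1.0:
        return 0.0 if k == n else -math.inf
    log_comb = (
        special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    )
    return float(log_comb + k * math.log(p) + (n - k) * math.log1p(-p))


def pmf(k: int, params: TrialParams) -> float:
    """P(X = k); convenience wrapper around :func:`log_pmf`."""
    lp = log_pmf(k, params)
    return 0.0 if lp == -math.inf else math.exp(lp)


def cdf(k: int, params: TrialParams) -> float:
    """Lower tail P(X <= k) through the regularized incomplete beta.

    P(X <= k) = I_{1-p}(n-k, k+1); ``cdf(n, .)`` is exactly 1.
    """
    n, p = params.n, params.p
    _check_k(k, n, upper=n)
    if k == n:
        return 1.0
    if p == 0.0:
        return 1.0
    if p == 1.0:
        return 0.0  # k < n here
    return float(special.betainc(n - k, k + 1, 1.0 - p))


def tail_geq(k: int, params: TrialParams) -> float:
    """Upper tail P(X >= k) = I_p(k, n-k+1).

    Accepts k in [0, n+1]: ``tail_geq(0, .)`` is exactly 1 (empty
    condition) and ``tail_geq(n+1, .)`` exactly 0.  Computed directly
    from the incomplete beta rather than as 1 - cdf, so small upper
    tails keep full relative precision.
    """
    n, p = params.n, params.p
    _check_k(k, n, upper=n + 1)
    if k == 0:
        return 1.0
    if k == n + 1:
        return 0.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    return float(special.betainc(k, n - k + 1, p))


def normal_tail_approx(k: int, params: TrialParams) -> float:
    """Gaussian approximation to P(X >= k), continuity-corrected.

    Diagnostic only: never used by the solvers, whose thresholds sit on
    tails near 1e-3 where the approximation error is material.
    """
    n, p = params.n, params.p
    _check_k(k, n, upper=n + 1)
    if p in (0.0, 1.0):
        return tail_geq(k, params)
    mu = n * p
    sd = math.sqrt(n * p * (1.0 - p))
    z = (k - 0.5 - mu) / sd
    return float(special.ndtr(-z))
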