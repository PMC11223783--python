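"""Binomial minimal-trusted-VAF coverage model.

At depth N with per-base error probability p, the number of alt reads
produced by sequencing error alone is Binomial(N, p).  The minimal
trusted alt-read count k* is the smallest k whose upper tail falls below
the significance level alpha,

    k* = min { k : P(X >= k) < alpha },  X ~ Binomial(N, p),

and the minimal trusted VAF is k*/N.  Calls whose alt support falls
below k* are flagged (never removed), and the mean of k*/N over covered
positions gives the per-sample mean detectable VAF reported by QC.

The tail is evaluated through the regularized incomplete beta function
(scipy's binomial survival function), which agrees with brute-force
summation of the probability mass to better than 1e-9 relative error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pileup import Pileup
from .snv import phred_to_error
from .variants import VariantCall

__all__ = [
    "MinVafResult",
    "min_alt_reads",
    "min_trusted_vaf",
    "flag_calls",
    "sample_mean_detectable_vaf",
]

LOW_VAF_FILTER = "low_vaf_for_coverage"


@dataclass(frozen=True)
class MinVafResult:
    pos: int | None
    depth: int
    mean_baseq: float
    error_p: float
    alpha: float
    k_star: int  # depth + 1 encodes "not achievable"
    min_vaf: float  # k_star / depth when achievable, else > 1

    @property
    def achievable(self) -> bool:
        return self.k_star <= self.depth


def _min_alt_reads_array(N: np.ndarray, p: float, alpha: float) -> np.ndarray:
    """Vectorized k* for an array of depths at one error probability."""
    N = np.asarray(N, dtype=np.int64)
    if p == 0.0:
        return np.ones_like(N)
    # start near the isf solution, then settle m = min{m : sf(m) < alpha}
    # exactly with bounded correction sweeps (isf is within +-1 of exact)
    m0 = stats.binom.isf(alpha, N, p)
    m = np.where(np.isfinite(m0), m0, N).astype(np.int64)
    m = np.clip(m, 0, N)
    for _ in range(4):
        bump = stats.binom.sf(m, N, p) >= alpha
        if not bump.any():
            break
        m = np.minimum(m + bump.astype(np.int64), N)
    for _ in range(4):
        back = (m >= 1) & (stats.binom.sf(m - 1, N, p) < alpha)
        if not back.any():
            break
        m = m - back.astype(np.int64)
    k = m + 1
    # unachievable: even k = N is not significant
    unach = stats.binom.sf(N - 1, N, p) >= alpha
    return np.where(unach, N + 1, k)


def min_alt_reads(N: int, p: float, alpha: float = 0.05) -> int:
    """Smallest k with P(X >= k) < alpha for X ~ Binomial(N, p).

    Returns N + 1 when no k <= N reaches significance.
    """
    if N < 1:
        raise ValueError("depth N must be >= 1")
    if not 0.0 <= p < 1.0:
        raise ValueError("error probability must be in [0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if p == 0.0:
        return 1
    # scan outward from the isf starting point; exact by construction
    start = int(stats.binom.isf(alpha, N, p))
    start = max(start - 2, 0)
    k = start + 1
    while k <= N and stats.binom.sf(k - 1, N, p) >= alpha:
        k += 1
    while k - 1 >= 1 and stats.binom.sf(k - 2, N, p) < alpha:
        k -= 1
    if k > N:
        return N + 1
    return k


def min_trusted_vaf(N: int, mean_baseq: float, alpha: float = 0.05, pos: int | None = None) -> MinVafResult:
    """Minimal trusted VAF at depth ``N`` and mean base quality ``mean_baseq``."""
    if N < 1:
        raise ValueError("minimal trusted VAF undefined at zero depth")
    p = phred_to_error(mean_baseq)
    k = min_alt_reads(N, p, alpha)
    return MinVafResult(
        pos=pos,
        depth=N,
        mean_baseq=mean_baseq,
        error_p=p,
        alpha=alpha,
        k_star=k,
        min_vaf=k / N,
    )


def flag_calls(
    calls: list[VariantCall], pileup: Pileup, alpha: float = 0.05
) -> list[VariantCall]:
    """Annotate calls whose alt support is statistically untrustworthy.

    A call whose alt read count falls below k*(depth, p(mean BQ), alpha)
    gains the ``low_vaf_for_coverage`` FILTER; nothing is removed.  The
    mean base quality over the alt-supporting observations is used when
    the call carries one, else the column mean.
    """
    for call in calls:
        if call.depth < 1:
            continue
        mbq = call.mean_baseq
        if mbq <= 0:
            mbq = float(pileup.mean_baseq[call.pos - 1])
        if mbq <= 0:
            continue
        res = min_trusted_vaf(call.depth, mbq, alpha, pos=call.pos)
        if call.alt_count < res.k_star:
            call.filters.discard("PASS")
            call.filters.add(LOW_VAF_FILTER)
    return calls


def sample_mean_detectable_vaf(pileup: Pileup, alpha: float = 0.05) -> float:
    """Mean of k*/N over covered positions — the sample's detection floor.

    Undefined (ValueError) when no position has coverage; QC reports
    that as the ``no_coverage`` exclusion reason.
    """
    depth = pileup.depth
    covered = depth > 0
    if not covered.any():
        raise ValueError("no covered positions: mean detectable VAF undefined")
    N = depth[covered].astype(np.int64)
    mbq = pileup.mean_baseq[covered]
    # group by rounded quality so each distinct error probability is one
    # vectorized evaluation
    qr = np.round(mbq, 1)
    min_vaf = np.empty(N.shape, dtype=float)
    for q in np.unique(qr):
        sel = qr == q
        p = phred_to_error(float(q))
        k = _min_alt_reads_array(N[sel], p, alpha)
        min_vaf[sel] = k / N[sel]
    return float(min_vaf.mean())
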