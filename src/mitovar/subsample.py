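"""Deterministic read subsampling to a target mean coverage.

The keep/drop decision for a read is a pure function of (seed, read
name): a keyed hash of the name is mapped to [0, 1) and the read is kept
when the value falls below the sampling fraction.  This makes the kept
set invariant under input reordering, keeps mate pairs (which share a
name) together, and makes re-runs with the same seed byte-identical —
no state is carried between reads.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Iterator

from .io_formats import AlignedRead

__all__ = ["DEFAULT_SEED", "subsample_fraction", "subsample_reads", "keep_read"]

DEFAULT_SEED = 42  # static seed: same input -> same subsample on every run

_DENOM = float(2**64)


def subsample_fraction(mean_cov: float, target_cov: float = 2000.0) -> float:
    """Fraction of reads required to bring ``mean_cov`` down to ``target_cov``.

    Clamped at 1.0 (samples already at or below target are untouched);
    zero mean coverage also maps to 1.0.
    """
    if mean_cov < 0 or target_cov <= 0:
        raise ValueError("coverages must be non-negative (target > 0)")
    if mean_cov == 0:
        return 1.0
    return min(1.0, target_cov / mean_cov)


def keep_read(name: str, fraction: float, seed: int = DEFAULT_SEED) -> bool:
    """Keep decision for one read name; pure in (seed, name, fraction)."""
    h = hashlib.blake2b(
        name.encode("utf-8"),
        digest_size=8,
        key=int(seed).to_bytes(16, "little", signed=False),
    )
    u = int.from_bytes(h.digest(), "big") / _DENOM
    return u < fraction


def subsample_reads(
    reads: Iterable[AlignedRead], fraction: float, seed: int = DEFAULT_SEED
) -> Iterator[AlignedRead]:
    """Yield the kept subset of ``reads`` at the given fraction.

    ``fraction == 1`` returns every read unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        yield from reads
        return
    for r in reads:
        if keep_read(r.name, fraction, seed):
            yield r
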