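"""Per-position, per-strand base observations — the substrate for both callers.

The pileup is stored as a dense count tensor indexed by
(position, strand, base, quality), which keeps the per-column observation
multiset exact while letting the bulk of reads (single-M CIGARs) be
accumulated with one vectorised ``bincount`` pass.  Reads with indels or
clips are walked individually.

The genome is treated as linear: reads are assumed pre-aligned and the
circularity of the mitochondrial genome (junction at positions 1/16569)
is a documented limitation, not handled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .io_formats import AlignedRead, Reference, parse_cigar

__all__ = [
    "PileupColumn",
    "IndelObservation",
    "Pileup",
    "build_pileup",
    "BASES",
    "base_code",
]

BASES = "ACGT"
QMAX = 93  # highest representable Phred score

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def base_code(base: str) -> int:
    c = _CODE[ord(base)]
    if c > 3:
        raise ValueError(f"not an ACGT base: {base!r}")
    return int(c)


@dataclass
class PileupColumn:
    """Quality-stratified base observations at one reference position."""

    pos: int  # 1-based
    ref_base: str
    counts: np.ndarray  # (2 strands, 4 bases) int
    qual_sum: np.ndarray  # (2, 4) summed Phred
    classes: list[tuple[int, int, int]]  # (base_code, qual, count) aggregated over strands

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_baseq(self) -> float:
        d = self.depth
        return float(self.qual_sum.sum()) / d if d else 0.0

    def base_counts(self) -> np.ndarray:
        """Strand-summed counts per base, shape (4,)."""
        return self.counts.sum(axis=0)

    def observations(self) -> Iterator[tuple[str, int, int]]:
        """Yield (base, qual, strand) for every retained observation."""
        # reconstructed from the count tensor slice; order is canonical,
        # not read order (the likelihood is order-invariant)
        for s in range(2):
            for b in range(4):
                n = int(self.counts[s, b])
                if n == 0:
                    continue
                # per-strand quality detail is not kept separately from the
                # aggregate classes; emit the strand-level mean quality
                q = int(round(self.qual_sum[s, b] / n))
                for _ in range(n):
                    yield BASES[b], q, s


@dataclass
class IndelObservation:
    """An insertion or deletion seen in reads, anchored at the base before it."""

    pos: int  # 1-based anchor (reference base preceding the event)
    kind: str  # "INS" or "DEL"
    seq: str  # inserted bases, or the deleted reference span
    count: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    depth_at_anchor: int = 0

    @property
    def total(self) -> int:
        return int(self.count.sum())


class Pileup:
    """Dense pileup over a single contig.

    ``counts_q[pos0, strand, base, qual]`` counts quality-passing base
    observations; derived per-column summaries are cached as arrays.
    """

    def __init__(
        self,
        reference: Reference,
        counts_q: np.ndarray,
        indels: list[IndelObservation],
        min_baseq: int,
        min_mapq: int,
        clipped_at_end: int = 0,
    ) -> None:
        self.reference = reference
        self.counts_q = counts_q
        self.indels = indels
        self.min_baseq = min_baseq
        self.min_mapq = min_mapq
        self.clipped_at_end = clipped_at_end

        self.counts = counts_q.sum(axis=3)  # (L, 2, 4)
        quals = np.arange(counts_q.shape[3], dtype=np.int64)
        self.qual_sum = (counts_q * quals).sum(axis=3)  # (L, 2, 4)
        self.depth = self.counts.sum(axis=(1, 2))  # (L,)
        with np.errstate(invalid="ignore"):
            self.mean_baseq = np.where(
                self.depth > 0, self.qual_sum.sum(axis=(1, 2)) / np.maximum(self.depth, 1), 0.0
            )
        for ind in self.indels:
            ind.depth_at_anchor = int(self.depth[ind.pos - 1])

    @property
    def length(self) -> int:
        return self.reference.length

    def column(self, pos: int) -> PileupColumn:
        """Materialise the column at 1-based position ``pos``."""
        i = pos - 1
        cq = self.counts_q[i]
        classes = []
        strand_sum = cq.sum(axis=0)  # (4, QMAX+1)
        bb, qq = np.nonzero(strand_sum)
        for b, q in zip(bb.tolist(), qq.tolist()):
            classes.append((b, q, int(strand_sum[b, q])))
        return PileupColumn(
            pos=pos,
            ref_base=self.reference.sequence[i],
            counts=self.counts[i],
            qual_sum=self.qual_sum[i],
            classes=classes,
        )

    def columns(self, min_depth: int = 0) -> Iterator[PileupColumn]:
        idx = np.nonzero(self.depth >= min_depth)[0] if min_depth else range(self.length)
        for i in idx:
            yield self.column(int(i) + 1)


def coverage_depth(
    reads: Iterable[AlignedRead],
    reference: Reference,
    min_baseq: int = 0,
    min_mapq: int = 0,
) -> np.ndarray:
    """Per-position aligned-base depth (CIGAR M/=/X), as an int64 array.

    With ``min_baseq == 0`` this uses a difference-array sweep over read
    spans and avoids materialising the full observation tensor; with a
    base-quality floor it falls back to the exact pileup.
    """
    reads = list(reads)
    if min_baseq > 0:
        pp = build_pileup(reads, reference, min_baseq=min_baseq, min_mapq=min_mapq)
        return pp.depth.astype(np.int64)
    L = reference.length
    diff = np.zeros(L + 1, dtype=np.int64)
    simple_starts: list[int] = []
    simple_ends: list[int] = []
    for r in reads:
        if r.mapq < min_mapq:
            continue
        mlen = _simple_m_length(r.cigar)
        if mlen is not None:
            s = r.pos - 1
            simple_starts.append(s)
            simple_ends.append(min(s + mlen, L))
        else:
            refpos = r.pos - 1
            for n, op in parse_cigar(r.cigar):
                if op in "M=X":
                    lo, hi = refpos, min(refpos + n, L)
                    if hi > lo:
                        diff[lo] += 1
                        diff[hi] -= 1
                    refpos += n
                elif op in "DN":
                    refpos += n
    if simple_starts:
        diff[:L] += np.bincount(
            np.asarray(simple_starts, dtype=np.int64), minlength=L
        )[:L]
        np.subtract.at(diff, np.asarray(simple_ends, dtype=np.int64), 1)
    return np.cumsum(diff[:L])


def _simple_m_length(cigar: str) -> int | None:
    """Read length if the CIGAR is a single M/=/X run, else None."""
    if cigar and cigar[-1] in "M=X" and cigar[:-1].isdigit():
        return int(cigar[:-1])
    return None


def build_pileup(
    reads: Iterable[AlignedRead],
    reference: Reference,
    min_baseq: int = 20,
    min_mapq: int = 20,
) -> Pileup:
    """Build the per-position observation tensor and indel observations.

    M/=/X CIGAR ops contribute base observations at their reference
    positions when the base quality and the read's mapping quality pass
    the floors; I ops create insertion observations anchored at the
    preceding reference position; D ops create deletion observations;
    soft clips and N bases contribute nothing.  Reads extending past the
    reference end are truncated and tallied in ``clipped_at_end``.
    """
    L = reference.length
    nq = QMAX + 1
    flat = np.zeros(L * 2 * 4 * nq, dtype=np.int64)

    simple: dict[int, list[AlignedRead]] = {}
    complex_reads: list[AlignedRead] = []
    clipped = 0
    for r in reads:
        if r.mapq < min_mapq:
            continue
        mlen = _simple_m_length(r.cigar)
        if mlen is not None and r.pos + mlen - 1 <= L:
            simple.setdefault(mlen, []).append(r)
        else:
            complex_reads.append(r)

    # vectorised path: stacks of equal-length pure-match reads; the key
    # packs (pos, strand, base, qual) into one int32 for a single bincount
    for rlen, batch in simple.items():
        n = len(batch)
        starts = np.fromiter((r.pos - 1 for r in batch), dtype=np.int32, count=n)
        strands = np.fromiter(
            (r.reverse_strand for r in batch), dtype=np.int32, count=n
        )
        bmat = np.frombuffer(
            "".join(r.bases for r in batch).encode("ascii"), dtype=np.uint8
        ).reshape(n, rlen)
        codes = _CODE[bmat]
        qmat = np.frombuffer(
            b"".join(r.quals.tobytes() for r in batch), dtype=np.uint8
        ).reshape(n, rlen)
        qmat = np.minimum(qmat, QMAX)
        key = np.empty((n, rlen), dtype=np.int32)
        np.add(starts[:, None], np.arange(rlen, dtype=np.int32)[None, :], out=key)
        key <<= 1
        key += strands[:, None]
        key <<= 2
        key += codes
        key *= nq
        key += qmat
        keep = (codes <= 3) & (qmat >= min_baseq)
        # bincount needs the native index dtype to stay on its fast path
        if keep.all():
            flat += np.bincount(key.ravel().astype(np.intp), minlength=flat.size)
        else:
            flat += np.bincount(key[keep].astype(np.intp), minlength=flat.size)

    # per-read path: indels, clips, reads overhanging the contig end
    indel_map: dict[tuple[int, str, str], np.ndarray] = {}
    extra_keys: list[int] = []
    seq = reference.sequence
    for r in complex_reads:
        refpos = r.pos - 1  # 0-based
        qpos = 0
        strand = 1 if r.reverse_strand else 0
        for n, op in parse_cigar(r.cigar):
            if op in "M=X":
                end = refpos + n
                if end > L:
                    clipped += 1
                    n = L - refpos
                    if n <= 0:
                        break
                    end = L
                codes = _CODE[
                    np.frombuffer(r.bases[qpos : qpos + n].encode("ascii"), dtype=np.uint8)
                ]
                quals = np.clip(r.quals[qpos : qpos + n].astype(np.int64), 0, QMAX)
                keep = (codes <= 3) & (quals >= min_baseq)
                pp = np.arange(refpos, refpos + n, dtype=np.int64)
                keys = (((pp * 2 + strand) * 4 + codes.astype(np.int64)) * nq + quals)[keep]
                extra_keys.append(keys)
                refpos += n
                qpos += n
            elif op == "I":
                anchor = refpos  # 1-based preceding reference base
                if anchor >= 1:
                    k = (anchor, "INS", r.bases[qpos : qpos + n])
                    indel_map.setdefault(k, np.zeros(2, dtype=np.int64))[strand] += 1
                qpos += n
            elif op == "D":
                anchor = refpos
                if refpos + n <= L and anchor >= 1:
                    k = (anchor, "DEL", seq[refpos : refpos + n])
                    indel_map.setdefault(k, np.zeros(2, dtype=np.int64))[strand] += 1
                else:
                    clipped += 1
                refpos += n
            elif op == "N":
                refpos += n
            elif op == "S":
                qpos += n
            # H and P consume nothing
            if refpos >= L and op in "M=XDN":
                pass
    if extra_keys:
        allk = np.concatenate(extra_keys)
        flat += np.bincount(allk, minlength=flat.size)

    counts_q = flat.reshape(L, 2, 4, nq).astype(np.int32)
    indels = [
        IndelObservation(pos=pos, kind=kind, seq=s, count=cnt)
        for (pos, kind, s), cnt in sorted(indel_map.items())
    ]
    return Pileup(
        reference,
        counts_q,
        indels,
        min_baseq=min_baseq,
        min_mapq=min_mapq,
        clipped_at_end=clipped,
    )
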