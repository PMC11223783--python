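"""Naive pileup indel caller.

Groups insertion/deletion observations by (anchor, kind, sequence) and
emits a call when the observation fraction against the anchor's base
depth clears the VAF floor with support on both strands.  Deliberately
simple: no haplotype assembly and no homopolymer-aware error model, so
it underperforms assembly-based callers on hard repeat contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import Reference
from .pileup import IndelObservation, Pileup
from .variants import VariantCall

__all__ = ["IndelParams", "call_indels"]


@dataclass
class IndelParams:
    min_vaf: float = 0.02
    min_count_per_strand: int = 2
    min_depth: int = 10


def call_indels(
    indel_obs: Iterable[IndelObservation],
    reference: Reference,
    params: IndelParams | None = None,
    mean_baseq_at: dict[int, float] | None = None,
) -> list[VariantCall]:
    """Turn grouped indel observations into anchor-base VCF-style calls.

    A DEL of span S after anchor p becomes (pos=p, ref=base(p)+S,
    alt=base(p)); an INS of S becomes (pos=p, ref=base(p),
    alt=base(p)+S).  Groups with zero anchor depth are skipped.
    """
    params = params or IndelParams()
    calls: list[VariantCall] = []
    for obs in indel_obs:
        depth = obs.depth_at_anchor
        if depth == 0 or depth < params.min_depth:
            continue
        total = obs.total
        vaf = total / depth
        if vaf > 1.0:
            vaf = 1.0
        if vaf < params.min_vaf:
            continue
        if int(obs.count[0]) < params.min_count_per_strand:
            continue
        if int(obs.count[1]) < params.min_count_per_strand:
            continue
        anchor_base = reference.base(obs.pos)
        if obs.kind == "INS":
            ref_allele, alt_allele, vtype = anchor_base, anchor_base + obs.seq, "INS"
        elif obs.kind == "DEL":
            ref_allele, alt_allele, vtype = anchor_base + obs.seq, anchor_base, "DEL"
        else:
            raise ValueError(f"unknown indel kind {obs.kind!r}")
        mbq = (mean_baseq_at or {}).get(obs.pos, 0.0)
        calls.append(
            VariantCall(
                pos=obs.pos,
                ref=ref_allele,
                alt=alt_allele,
                type=vtype,
                vaf=vaf,
                depth=depth,
                mean_baseq=mbq,
                strand_counts=(int(obs.count[0]), int(obs.count[1])),
                source="indel-standin",
                genotype="1/1" if vaf > 0.95 else "0/1",
            )
        )
    calls.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return calls


def call_indels_from_pileup(
    pileup: Pileup, params: IndelParams | None = None
) -> list[VariantCall]:
    """Convenience wrapper using the pileup's observations and base qualities."""
    mbq = {
        obs.pos: float(pileup.mean_baseq[obs.pos - 1]) for obs in pileup.indels
    }
    return call_indels(pileup.indels, pileup.reference, params, mean_baseq_at=mbq)
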