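"""Variant normalization, multiallelic splitting and the fusion merge.

The fusion merge combines two call sets: SNVs from the Bayesian caller
and indels from an indel caller (the built-in stand-in, or any external
indel VCF).  Both sets are first left-aligned to their parsimonious
representation and split into biallelic records; when both callers
report a variant at the same position, the indel wins.
"""

from __future__ import annotations

from typing import Sequence

from .io_formats import Reference, VcfRecord
from .variants import VariantCall, classify_alleles

__all__ = [
    "split_multiallelic",
    "normalize_variant",
    "normalize_alleles",
    "merge_fusion",
]

_PER_ALLELE_KEYS = {"AF", "TYPE"}


def split_multiallelic(record: VcfRecord) -> list[VcfRecord]:
    """One biallelic record per ALT allele, preserving per-allele AF.

    Biallelic records come back unchanged (as a singleton list); alt
    order is preserved.
    """
    if len(record.alts) <= 1:
        return [record]
    out = []
    for i, alt in enumerate(record.alts):
        info = {}
        for key, val in record.info.items():
            if key in _PER_ALLELE_KEYS and isinstance(val, (list, tuple)):
                info[key] = val[i]
            else:
                info[key] = val
        sample_fields = {}
        for key, val in record.sample_fields.items():
            if key in _PER_ALLELE_KEYS and isinstance(val, (list, tuple)):
                sample_fields[key] = val[i]
            else:
                sample_fields[key] = val
        out.append(
            VcfRecord(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alts=[alt],
                qual=record.qual,
                filters=set(record.filters),
                info=info,
                sample_fields=sample_fields,
            )
        )
    return out


def normalize_alleles(
    pos: int, ref: str, alt: str, reference: Reference
) -> tuple[int, str, str]:
    """Left-align and trim one (pos, ref, alt) pair to canonical form.

    Standard parsimony/left-alignment: repeatedly drop a shared trailing
    base (extending left from the reference when an allele would empty),
    then trim shared leading bases.  SNVs pass through unchanged.  The
    procedure is idempotent.
    """
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    seq = reference.sequence
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and max(len(ref), len(alt)) >= 2:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos <= 1:
                raise ValueError("cannot left-extend past contig start")
            pos -= 1
            b = seq[pos - 1]
            ref, alt = b + ref, b + alt
            changed = True
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(record: VcfRecord, reference: Reference) -> VcfRecord:
    """Normalize a biallelic :class:`VcfRecord` (see :func:`normalize_alleles`)."""
    if len(record.alts) != 1:
        raise ValueError("normalize_variant requires a biallelic record")
    pos, ref, alt = normalize_alleles(record.pos, record.ref, record.alts[0], reference)
    if (pos, ref, [alt]) == (record.pos, record.ref, record.alts):
        return record
    return VcfRecord(
        chrom=record.chrom,
        pos=pos,
        ref=ref,
        alts=[alt],
        qual=record.qual,
        filters=set(record.filters),
        info=dict(record.info),
        sample_fields=dict(record.sample_fields),
    )


def _is_normalized(ref: str, alt: str) -> bool:
    if len(ref) >= 1 and len(alt) >= 1 and max(len(ref), len(alt)) >= 2:
        if ref[-1] == alt[-1]:
            return False
    if len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        return False
    return True


def merge_fusion(
    snv_calls: Sequence[VariantCall], indel_calls: Sequence[VariantCall]
) -> list[VariantCall]:
    """Fuse the two call sets: indels from the indel caller, SNVs from
    the Bayesian caller; on a positional collision the indel is favored.

    SNV-type records in the indel caller's output are discarded — SNVs
    come only from the Bayesian caller.  Inputs must be normalized and
    biallelic; a record with detectable shared leading/trailing allele
    bases is rejected.
    """
    for c in list(snv_calls) + list(indel_calls):
        if not _is_normalized(c.ref, c.alt):
            raise ValueError(
                f"unnormalized call at pos {c.pos}: {c.ref}>{c.alt} "
                "(run normalization first)"
            )
    kept_indels = [c for c in indel_calls if classify_alleles(c.ref, c.alt) != "SNV"]
    indel_positions = {c.pos for c in kept_indels}
    kept_snvs = [
        c
        for c in snv_calls
        if classify_alleles(c.ref, c.alt) == "SNV" and c.pos not in indel_positions
    ]
    merged: dict[tuple[int, str, str], VariantCall] = {}
    for c in kept_indels + kept_snvs:
        merged.setdefault(c.key, c)
    return sorted(merged.values(), key=lambda c: (c.pos, c.ref, c.alt))
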