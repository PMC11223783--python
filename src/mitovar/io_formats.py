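"""Readers and writers for the standard formats the toolkit touches.

FASTA references (single mitochondrial contig), SAM/BAM alignments and
VCF 4.2 call sets.  SAM text is the mandatory interchange; BAM works
wherever pysam provides the codec.  All coordinates in the public types
are 1-based inclusive, following the VCF convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

__all__ = [
    "Reference",
    "AlignedRead",
    "VcfRecord",
    "ReadSet",
    "read_fasta",
    "read_alignments",
    "write_sam",
    "read_vcf",
    "write_vcf",
]

_VALID_REF_CHARS = set("ACGTN")

# CIGAR operations that consume query / reference bases
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class Reference:
    """A single mitochondrial contig (rCRS-like) with per-base access."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference name must be non-empty")
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - _VALID_REF_CHARS
        if bad:
            raise ValueError(f"reference contains invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside contig of length {self.length}")
        return self.sequence[pos - 1]


@dataclass
class AlignedRead:
    """One mapped read in reference orientation.

    ``pos`` is the 1-based leftmost mapped position.  ``bases`` and
    ``quals`` are query-length aligned; the CIGAR string relates them to
    the reference.
    """

    name: str
    pos: int
    cigar: str
    bases: str
    quals: np.ndarray  # per-base Phred, uint8
    mapq: int = 60
    reverse_strand: bool = False
    flags: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.quals, np.ndarray):
            self.quals = np.asarray(self.quals, dtype=np.uint8)
        if self.pos < 1:
            raise ValueError(f"read {self.name}: pos must be >= 1, got {self.pos}")
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.name}: bases/quals length mismatch")
        qlen = cigar_query_length(self.cigar)
        if qlen != len(self.bases):
            raise ValueError(
                f"read {self.name}: CIGAR consumes {qlen} query bases, sequence has {len(self.bases)}"
            )


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples."""
    ops: list[tuple[int, str]] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        elif ch in "MIDNSHP=X":
            if n == 0:
                raise ValueError(f"zero-length CIGAR op in {cigar!r}")
            ops.append((n, ch))
            n = 0
        else:
            raise ValueError(f"invalid CIGAR character {ch!r} in {cigar!r}")
    if n:
        raise ValueError(f"trailing length without op in CIGAR {cigar!r}")
    if not ops:
        raise ValueError("empty CIGAR")
    return ops


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in _QUERY_OPS)


def cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in _REF_OPS)


def read_fasta(path: str | os.PathLike) -> Reference:
    """Read a single-record FASTA into a :class:`Reference`.

    Multi-record files are rejected: this tool operates on exactly one
    mitochondrial contig.
    """
    names: list[str] = []
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if names:
                    extra = line[1:].split()[0] if len(line) > 1 else "?"
                    raise ValueError(
                        f"multiple contigs in {path}: expected a single record, "
                        f"also found {extra!r}"
                    )
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}: FASTA header has no name")
                names.append(header.split()[0])
            else:
                if not names:
                    raise ValueError(f"{path}: sequence before FASTA header")
                chunks.append(line.strip())
    if not names:
        raise ValueError(f"{path}: no FASTA record found")
    seq = "".join(chunks).upper()
    if not seq:
        raise ValueError(f"{path}: empty sequence for contig {names[0]!r}")
    return Reference(name=names[0], sequence=seq)


def write_fasta(reference: Reference, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{reference.name}\n")
        for i in range(0, reference.length, width):
            fh.write(reference.sequence[i : i + width] + "\n")


@dataclass
class ReadSet:
    """Alignments loaded from one sample plus bookkeeping for QC."""

    reads: list[AlignedRead]
    header_contigs: set[str] = field(default_factory=set)
    read_contigs: set[str] = field(default_factory=set)
    malformed: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_duplicate: int = 0

    def __iter__(self) -> Iterator[AlignedRead]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def read_alignments(
    path: str | os.PathLike,
    region: str | None = None,
    exclude_duplicates: bool = True,
) -> ReadSet:
    """Load mapped primary reads from a SAM (or BAM) file.

    Unmapped, secondary and supplementary reads are always skipped;
    duplicate-flagged reads are skipped by default.  Reads whose CIGAR
    does not match their sequence length are counted as malformed and
    dropped, surfaced to QC via :attr:`ReadSet.malformed`.
    """
    rs = ReadSet(reads=[])
    if str(path).endswith(".bam"):
        with pysam.AlignmentFile(str(path), "rb", check_sq=False) as fh:
            rs.header_contigs = set(fh.references or ())
            it = fh.fetch(region=region) if region else fh
            for aln in it:
                _collect(aln, rs, region, exclude_duplicates)
        return rs
    # SAM text is parsed line-wise so a malformed record can be tallied
    # and skipped instead of aborting the whole stream
    header_lines: list[str] = []
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            (header_lines if line.startswith("@") else body).append(line)
    header = pysam.AlignmentHeader.from_text("\n".join(header_lines) + "\n")
    rs.header_contigs = set(header.references or ())
    for line in body:
        try:
            aln = pysam.AlignedSegment.fromstring(line, header)
        except Exception:
            rs.malformed += 1
            continue
        _collect(aln, rs, region, exclude_duplicates)
    return rs


def _collect(
    aln: "pysam.AlignedSegment", rs: ReadSet, region: str | None, exclude_duplicates: bool
) -> None:
    if aln.is_unmapped:
        rs.skipped_unmapped += 1
        return
    if region and aln.reference_name != region:
        return
    if aln.is_secondary or aln.is_supplementary:
        rs.skipped_secondary += 1
        return
    if exclude_duplicates and aln.is_duplicate:
        rs.skipped_duplicate += 1
        return
    seq = aln.query_sequence
    if seq is None or aln.cigarstring is None:
        rs.malformed += 1
        return
    quals = aln.query_qualities
    if quals is None:
        quals = np.full(len(seq), 30, dtype=np.uint8)
    try:
        read = AlignedRead(
            name=aln.query_name,
            pos=aln.reference_start + 1,
            cigar=aln.cigarstring,
            bases=seq.upper(),
            quals=np.asarray(quals, dtype=np.uint8),
            mapq=aln.mapping_quality,
            reverse_strand=aln.is_reverse,
            flags=aln.flag,
        )
    except ValueError:
        rs.malformed += 1
        return
    rs.read_contigs.add(aln.reference_name)
    rs.reads.append(read)


def write_sam(
    reads: Iterable[AlignedRead], reference: Reference, path: str | os.PathLike
) -> None:
    """Write reads as a SAM file with an @HD/@SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference.name, "LN": reference.length}],
    }
    mode = "wb" if str(path).endswith(".bam") else "wh"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.query_sequence = r.bases
            a.query_qualities = [int(q) for q in r.quals]
            a.reference_id = 0
            a.reference_start = r.pos - 1
            a.cigarstring = r.cigar
            a.mapping_quality = r.mapq
            a.flag = r.flags | (16 if r.reverse_strand else 0)
            out.write(a)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_MISSING = None


@dataclass
class VcfRecord:
    """A VCF site with one sample column."""

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    qual: float | None = None
    filters: set[str] = field(default_factory=lambda: {"PASS"})
    info: dict = field(default_factory=dict)
    sample_fields: dict = field(default_factory=dict)
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or set(self.ref) - _VALID_REF_CHARS:
            raise ValueError(f"invalid REF allele {self.ref!r}")
        for alt in self.alts:
            if not alt:
                raise ValueError("empty ALT allele")
        if self.pos < 1:
            raise ValueError("POS must be >= 1")


_DECLARED_INFO = {
    "MEAN_BQ": ("1", "Float", "Mean Phred base quality of alt-supporting observations"),
    "SRC": ("1", "String", "Caller that produced the record"),
    "TYPE": ("1", "String", "Variant type (SNV, INS or DEL)"),
}
_DECLARED_FORMAT = {
    "GT": ("1", "String", "Genotype"),
    "DP": ("1", "Integer", "Read depth at the site"),
    "AF": ("1", "Float", "Variant allele frequency"),
}
_DECLARED_FILTERS = {
    "low_vaf_for_coverage": "Coverage/base quality do not statistically support the observed VAF",
    "strand_bias": "Alt allele support confined to one strand",
}


def _build_vcf_header(reference: Reference, sample: str) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={reference.name},length={reference.length}>")
    for fid, desc in _DECLARED_FILTERS.items():
        h.add_meta("FILTER", items=[("ID", fid), ("Description", desc)])
    for key, (num, typ, desc) in _DECLARED_INFO.items():
        h.add_meta(
            "INFO",
            items=[("ID", key), ("Number", num), ("Type", typ), ("Description", desc)],
        )
    for key, (num, typ, desc) in _DECLARED_FORMAT.items():
        h.add_meta(
            "FORMAT",
            items=[("ID", key), ("Number", num), ("Type", typ), ("Description", desc)],
        )
    h.add_sample(sample)
    return h


def write_vcf(
    records: list[VcfRecord],
    reference: Reference,
    path: str | os.PathLike,
    sample: str = "SAMPLE",
) -> None:
    """Write records as VCF 4.2 text.

    Records must be position-sorted; INFO/FILTER keys must be among the
    declared set (PASS, low_vaf_for_coverage, strand_bias; MEAN_BQ, SRC,
    TYPE).  Round-trips with :func:`read_vcf` on pos/ref/alt/filters and
    AF to four decimal places.
    """
    positions = [r.pos for r in records]
    if positions != sorted(positions):
        raise ValueError("VCF records must be sorted by position")
    for r in records:
        for key in r.info:
            if key not in _DECLARED_INFO:
                raise ValueError(f"undeclared INFO key {key!r}")
        for f in r.filters:
            if f != "PASS" and f not in _DECLARED_FILTERS:
                raise ValueError(f"undeclared FILTER key {f!r}")
        for key in r.sample_fields:
            if key not in _DECLARED_FORMAT:
                raise ValueError(f"undeclared FORMAT key {key!r}")
    header = _build_vcf_header(reference, sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=reference.name,
                start=r.pos - 1,
                alleles=(r.ref, *r.alts),
            )
            if r.qual is not None:
                rec.qual = r.qual
            for f in sorted(r.filters):
                rec.filter.add(f)
            for key, val in r.info.items():
                rec.info[key] = val
            smp = rec.samples[sample]
            for key, val in r.sample_fields.items():
                if key == "GT":
                    smp["GT"] = tuple(
                        None if x == "." else int(x)
                        for x in str(val).replace("|", "/").split("/")
                    )
                elif key == "AF":
                    smp[key] = round(float(val), 4)
                else:
                    smp[key] = val
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> list[VcfRecord]:
    """Read a VCF file into :class:`VcfRecord` objects."""
    out: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as fh:
        samples = list(fh.header.samples)
        for rec in fh:
            filters = set(rec.filter.keys()) or {"PASS"}
            info = {}
            for key, val in rec.info.items():
                if isinstance(val, tuple) and len(val) == 1:
                    val = val[0]
                info[key] = val
            sample_fields: dict = {}
            if samples:
                smp = rec.samples[samples[0]]
                for key in smp.keys():
                    val = smp[key]
                    if key == "GT":
                        val = "/".join("." if x is None else str(x) for x in val)
                    elif isinstance(val, tuple) and len(val) == 1:
                        val = val[0]
                    if val is not None:
                        sample_fields[key] = val
            out.append(
                VcfRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=list(rec.alts or ()),
                    qual=rec.qual,
                    filters=filters,
                    info=info,
                    sample_fields=sample_fields,
                )
            )
    return out
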