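"""Per-sample input validation and quality control.

Each sample is checked before calling: is it aligned to a mitochondrial
contig, is the mean coverage sufficient, and are read/base/mapping
quality statistics acceptable.  All checks always run, so an excluded
sample reports every reason at once, and the statistics are filled in
regardless of the pass/fail outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import AlignedRead, ReadSet, Reference
from .pileup import coverage_depth

__all__ = ["QCThresholds", "QCReport", "mean_coverage", "validate_sample"]

# common names for the human mitochondrial contig; user-overridable
DEFAULT_MT_CONTIGS = frozenset({"chrM", "MT", "chrMT", "NC_012920.1", "rCRS"})


@dataclass
class QCThresholds:
    expected_contigs: frozenset = DEFAULT_MT_CONTIGS
    min_mean_coverage: float = 50.0
    min_mean_baseq: float = 10.0
    min_mean_mapq: float = 10.0


@dataclass
class QCReport:
    sample_id: str
    passed: bool = False
    exclusion_reasons: list = field(default_factory=list)
    contig_seen: str = ""
    mean_coverage: float = 0.0
    median_coverage: float = 0.0
    mean_mapq: float = 0.0
    mean_baseq: float = 0.0
    pct_bases_ge_q20: float = 0.0
    read_count: int = 0
    malformed_reads: int = 0
    mean_detectable_vaf: float | None = None  # filled by the coverage model

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self) -> dict:
        d = asdict(self)
        d["exclusion_reasons"] = ";".join(self.exclusion_reasons)
        return d


def mean_coverage(
    reads,
    reference: Reference,
    min_baseq: int = 0,
    min_mapq: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-position base depth and its mean over the contig.

    Depth counts reference-aligned bases (CIGAR M/=/X) passing both
    quality floors; deletions contribute nothing.  An empty read stream
    gives an all-zero depth array.
    """
    depth = coverage_depth(list(reads), reference, min_baseq=min_baseq, min_mapq=min_mapq)
    return depth, float(depth.sum() / reference.length)


def validate_sample(
    reads: ReadSet | list[AlignedRead],
    reference: Reference,
    thresholds: QCThresholds | None = None,
    sample_id: str = "sample",
) -> QCReport:
    """Run every QC check and return the full report.

    Exclusion reasons accumulate: ``wrong_contig`` when the sample's
    contig is not an accepted mitochondrial name, ``low_coverage`` /
    ``low_baseq`` / ``low_mapq`` when the respective mean falls below
    its floor, ``no_reads`` for an empty sample.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(sample_id=sample_id)

    if isinstance(reads, ReadSet):
        read_list = reads.reads
        report.malformed_reads = reads.malformed
        contigs = reads.read_contigs or reads.header_contigs
        report.contig_seen = ",".join(sorted(contigs)) if contigs else reference.name
        sample_contigs = contigs or {reference.name}
    else:
        read_list = list(reads)
        report.contig_seen = reference.name
        sample_contigs = {reference.name}

    report.read_count = len(read_list)
    reasons = report.exclusion_reasons

    if not sample_contigs & set(thresholds.expected_contigs):
        reasons.append("wrong_contig")

    if read_list:
        nb = np.array([len(r.bases) for r in read_list], dtype=np.int64)
        qs = np.array([int(r.quals.sum()) for r in read_list], dtype=np.int64)
        q20 = np.array([int((r.quals >= 20).sum()) for r in read_list], dtype=np.int64)
        total = int(nb.sum())
        report.mean_baseq = float(qs.sum() / total)
        report.pct_bases_ge_q20 = 100.0 * float(q20.sum() / total)
        report.mean_mapq = float(np.mean([r.mapq for r in read_list]))
    else:
        reasons.append("no_reads")

    depth, mean_cov = mean_coverage(read_list, reference)
    report.mean_coverage = mean_cov
    report.median_coverage = float(np.median(depth))

    if mean_cov < thresholds.min_mean_coverage:
        reasons.append("low_coverage")
    if read_list and report.mean_baseq < thresholds.min_mean_baseq:
        reasons.append("low_baseq")
    if read_list and report.mean_mapq < thresholds.min_mean_mapq:
        reasons.append("low_mapq")

    report.passed = not reasons
    return report
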