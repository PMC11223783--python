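"""Per-sample workflow: validate -> (subsample) -> pileup -> call -> flag -> report.

Three calling modes are available: ``snv`` (Bayesian caller only),
``indel`` (pileup indel caller only) and ``fusion`` (both, merged with
indels winning positional conflicts).  Samples are independent, so any
batch can be processed in any order — or concurrently — with output
identical to a sequential run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .coverage import flag_calls, sample_mean_detectable_vaf
from .fusion import merge_fusion
from .indels import IndelParams, call_indels_from_pileup
from .io_formats import AlignedRead, ReadSet, Reference, VcfRecord
from .pileup import build_pileup
from .qc import QCReport, QCThresholds, validate_sample
from .snv import CallerParams, PriorTable, call_snvs
from .subsample import DEFAULT_SEED, subsample_fraction, subsample_reads
from .variants import VariantCall

__all__ = ["PipelineParams", "SampleResult", "run_sample", "summarize_batch", "calls_to_vcf_records"]

MODES = ("snv", "indel", "fusion")


@dataclass
class PipelineParams:
    mode: str = "fusion"
    min_vaf: float = 0.02
    min_minor_per_strand: int = 2
    min_depth: int = 10
    min_baseq: int = 20
    min_mapq: int = 20
    subsample: bool = False
    target_coverage: float = 2000.0
    subsample_seed: int = DEFAULT_SEED
    min_vaf_check: bool = False
    alpha: float = 0.05
    priors: PriorTable | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)

    def as_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("priors", "qc")
        }
        d.update({f"qc_{k}": (sorted(v) if isinstance(v, frozenset) else v)
                  for k, v in self.qc.__dict__.items()})
        return d


@dataclass
class SampleResult:
    sample_id: str
    qc: QCReport
    excluded: bool
    calls: list[VariantCall] | None = None
    snv_calls: list[VariantCall] | None = None
    indel_calls: list[VariantCall] | None = None
    summary: dict = field(default_factory=dict)


def run_sample(
    reads: ReadSet | Sequence[AlignedRead],
    reference: Reference,
    params: PipelineParams | None = None,
    sample_id: str = "sample",
) -> SampleResult:
    """Run the full per-sample workflow and return calls plus reports.

    A sample failing input validation is returned excluded, with its QC
    report filled and no calls — callers can distinguish "excluded" from
    a crash by the :attr:`SampleResult.excluded` flag.
    """
    params = params or PipelineParams()
    if params.mode not in MODES:
        raise ValueError(f"unknown mode {params.mode!r}; expected one of {MODES}")

    qc_report = validate_sample(reads, reference, params.qc, sample_id=sample_id)
    read_list = reads.reads if isinstance(reads, ReadSet) else list(reads)

    if not qc_report.passed:
        return SampleResult(
            sample_id=sample_id,
            qc=qc_report,
            excluded=True,
            summary=_summary(sample_id, params, qc_report, None, None, None),
        )

    if params.subsample:
        frac = subsample_fraction(qc_report.mean_coverage, params.target_coverage)
        read_list = list(subsample_reads(read_list, frac, params.subsample_seed))

    pp = build_pileup(
        read_list, reference, min_baseq=params.min_baseq, min_mapq=params.min_mapq
    )

    caller_params = CallerParams(
        min_vaf=params.min_vaf,
        min_minor_per_strand=params.min_minor_per_strand,
        min_depth=params.min_depth,
    )
    indel_params = IndelParams(
        min_vaf=params.min_vaf,
        min_count_per_strand=params.min_minor_per_strand,
        min_depth=params.min_depth,
    )

    snv_calls = indel_calls = None
    if params.mode in ("snv", "fusion"):
        snv_calls = call_snvs(pp, reference, params.priors, caller_params)
    if params.mode in ("indel", "fusion"):
        indel_calls = call_indels_from_pileup(pp, indel_params)

    if params.mode == "snv":
        calls = list(snv_calls)
    elif params.mode == "indel":
        calls = list(indel_calls)
    else:
        calls = merge_fusion(snv_calls, indel_calls)

    if params.min_vaf_check:
        calls = flag_calls(calls, pp, alpha=params.alpha)
    try:
        qc_report.mean_detectable_vaf = sample_mean_detectable_vaf(pp, params.alpha)
    except ValueError:
        qc_report.exclusion_reasons.append("no_coverage")
        qc_report.passed = False

    return SampleResult(
        sample_id=sample_id,
        qc=qc_report,
        excluded=False,
        calls=calls,
        snv_calls=snv_calls,
        indel_calls=indel_calls,
        summary=_summary(sample_id, params, qc_report, calls, snv_calls, indel_calls),
    )


def _summary(sample_id, params, qc_report, calls, snv_calls, indel_calls) -> dict:
    n_snv = sum(1 for c in calls or () if c.type == "SNV")
    n_indel = sum(1 for c in calls or () if c.type in ("INS", "DEL"))
    n_flagged = sum(1 for c in calls or () if "PASS" not in c.filters)
    return {
        "sample": sample_id,
        "mode": params.mode,
        "passed_qc": qc_report.passed,
        "exclusion_reasons": ";".join(qc_report.exclusion_reasons),
        "n_snv": n_snv,
        "n_indel": n_indel,
        "n_flagged": n_flagged,
        "mean_coverage": qc_report.mean_coverage,
        "mean_detectable_vaf": qc_report.mean_detectable_vaf,
        "params": params.as_dict(),
    }


def calls_to_vcf_records(
    calls: Sequence[VariantCall], reference: Reference
) -> list[VcfRecord]:
    """VariantCall -> VcfRecord with GT/DP/AF and MEAN_BQ/SRC/TYPE annotations."""
    records = []
    for c in sorted(calls, key=lambda c: (c.pos, c.ref, c.alt)):
        records.append(
            VcfRecord(
                chrom=reference.name,
                pos=c.pos,
                ref=c.ref,
                alts=[c.alt],
                filters=set(c.filters),
                info={
                    "MEAN_BQ": round(float(c.mean_baseq), 2),
                    "SRC": c.source or "unknown",
                    "TYPE": c.type,
                },
                sample_fields={
                    "GT": c.genotype,
                    "DP": int(c.depth),
                    "AF": round(float(c.vaf), 4),
                },
            )
        )
    return records


def summarize_batch(summaries: Sequence[dict]) -> pd.DataFrame:
    """One row per sample: pass/fail, reasons, coverage, call counts.

    The full parameter set used is carried in each summary so a run can
    be reproduced from its report alone.
    """
    if not summaries:
        raise ValueError("summarize_batch requires at least one sample summary")
    rows = []
    for s in summaries:
        row = {k: v for k, v in s.items() if k != "params"}
        row["params"] = json.dumps(s.get("params", {}), sort_keys=True)
        rows.append(row)
    return pd.DataFrame(rows)
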