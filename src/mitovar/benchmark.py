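"""Regenerate the gold-standard benchmark and score the callers against it.

One seeded run simulates a batch of samples on a mitochondrial-sized
reference, each carrying heteroplasmic SNVs and short indels at VAFs of
at least 2%, calls variants in every mode via the standard per-sample
pipeline, and scores calls against the truth sets.  The defaults are the
benchmark design: 30 samples, 35 SNVs + 8 indels each, 2000x coverage,
Q30 single-end 150 bp reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import PipelineParams, run_sample
from .simulate import (
    EvalResult,
    SimulationSpec,
    evaluate_calls,
    simulate_reads,
    simulate_reference,
    spike_variants,
)

__all__ = ["SampleScore", "BenchmarkResult", "run_benchmark"]


@dataclass
class SampleScore:
    sample_id: str
    n_truth: int
    n_truth_snv: int
    n_truth_indel: int
    fusion: EvalResult
    snv_only: EvalResult
    indel_only: EvalResult


@dataclass
class BenchmarkResult:
    spec: SimulationSpec
    samples: list[SampleScore] = field(default_factory=list)

    def mean(self, mode: str, category: str, metric: str) -> float:
        """Per-sample mean of a metric, e.g. mean('fusion', 'all', 'all_sites')."""
        vals = []
        for s in self.samples:
            res: EvalResult = getattr(s, mode)
            vals.append(res.as_dict()[category][metric])
        return float(np.mean(vals))

    def table(self) -> list[dict]:
        """Long-format rows: mode x category x metrics, one block per sample."""
        rows = []
        for s in self.samples:
            for mode in ("fusion", "snv_only", "indel_only"):
                for cat, counts in getattr(s, mode).as_dict().items():
                    rows.append(
                        {"sample": s.sample_id, "mode": mode, "category": cat, **counts}
                    )
        return rows


def run_benchmark(
    seed: int,
    spec: SimulationSpec | None = None,
    params: PipelineParams | None = None,
) -> BenchmarkResult:
    """Simulate ``spec.n_samples`` samples and score every calling mode.

    The fusion-mode pipeline run also yields the SNV-only and indel-only
    call sets (fusion is their merge), so each sample is simulated and
    piled up exactly once.  All randomness derives from ``seed``.
    """
    spec = spec or SimulationSpec()
    children = np.random.SeedSequence(seed).generate_state(2 * spec.n_samples + 1)
    children = (children % np.uint32(2**31)).astype(np.int64)
    reference = simulate_reference(spec.ref_length, seed=int(children[0]))
    base_params = params or PipelineParams()
    if base_params.mode != "fusion":
        raise ValueError("run_benchmark scores all modes at once; params.mode must be 'fusion'")

    result = BenchmarkResult(spec=spec)
    for i in range(spec.n_samples):
        sid = f"sample{i:02d}"
        truth = spike_variants(
            reference,
            spec.n_snvs,
            spec.n_indels,
            seed=int(children[1 + 2 * i]),
            vaf_range=spec.vaf_range,
            min_spacing=spec.min_spacing,
            max_indel_len=spec.max_indel_len,
        )
        reads = simulate_reads(
            reference,
            truth,
            spec.coverage,
            read_len=spec.read_len,
            base_qual=spec.base_qual,
            sequencing_errors=spec.sequencing_errors,
            seed=int(children[2 + 2 * i]),
            name_prefix=f"{sid}_",
        )
        run = run_sample(reads, reference, base_params, sample_id=sid)
        if run.excluded:
            raise RuntimeError(f"{sid} unexpectedly failed QC: {run.qc.exclusion_reasons}")
        result.samples.append(
            SampleScore(
                sample_id=sid,
                n_truth=len(truth),
                n_truth_snv=sum(v.type == "SNV" for v in truth),
                n_truth_indel=sum(v.type != "SNV" for v in truth),
                fusion=evaluate_calls(run.calls, truth),
                snv_only=evaluate_calls(run.snv_calls, truth),
                indel_only=evaluate_calls(run.indel_calls, truth),
            )
        )
    return result
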