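"""Simulator determinism, truth-set structure and evaluation accounting."""

import numpy as np
import pytest

from mitovar import (
    Reference,
    build_pileup,
    call_snvs,
    evaluate_calls,
    simulate_reads,
    simulate_reference,
    spike_variants,
)
from mitovar.fusion import normalize_alleles
from mitovar.simulate import TruthVariant
from mitovar.variants import VariantCall


class TestReference:
    def test_length_and_determinism(self):
        a = simulate_reference(16569, seed=5)
        b = simulate_reference(16569, seed=5)
        assert a.length == 16569
        assert a.sequence == b.sequence
        assert simulate_reference(16569, seed=6).sequence != a.sequence

    def test_base_composition_near_uniform(self):
        ref = simulate_reference(16569, seed=5)
        for base in "ACGT":
            frac = ref.sequence.count(base) / ref.length
            assert 0.24 <= frac <= 0.26


class TestSpikeVariants:
    def test_requested_counts(self):
        ref = simulate_reference(16569, seed=1)
        truth = spike_variants(ref, 35, 8, seed=1)
        assert len(truth) == 43
        assert sum(v.type == "SNV" for v in truth) == 35
        assert sum(v.type in ("INS", "DEL") for v in truth) == 8

    def test_zero_variants(self):
        ref = simulate_reference(1000, seed=1)
        assert spike_variants(ref, 0, 0, seed=1) == []

    def test_truth_records_are_normalization_fixpoints(self):
        ref = simulate_reference(16569, seed=2)
        for v in spike_variants(ref, 20, 20, seed=2):
            assert normalize_alleles(v.pos, v.ref, v.alt, ref) == (v.pos, v.ref, v.alt)

    def test_positions_respect_spacing(self):
        ref = simulate_reference(16569, seed=3)
        truth = spike_variants(ref, 35, 8, seed=3, min_spacing=10)
        positions = sorted(v.pos for v in truth)
        assert min(np.diff(positions)) >= 10

    def test_infeasible_spacing_rejected(self):
        ref = simulate_reference(200, seed=1)
        with pytest.raises(ValueError):
            spike_variants(ref, 50, 10, seed=1)

    def test_vafs_within_requested_range(self):
        ref = simulate_reference(16569, seed=4)
        truth = spike_variants(ref, 30, 10, seed=4, vaf_range=(0.02, 0.5))
        assert all(0.02 <= v.target_vaf <= 0.5 for v in truth)


class TestSimulateReads:
    def test_full_determinism(self):
        ref = simulate_reference(2000, seed=7)
        truth = spike_variants(ref, 5, 2, seed=7)
        a = simulate_reads(ref, truth, coverage=50, read_len=100, seed=7)
        b = simulate_reads(ref, truth, coverage=50, read_len=100, seed=7)
        assert len(a) == len(b)
        assert all(
            (x.pos, x.cigar, x.bases, x.reverse_strand) == (y.pos, y.cigar, y.bases, y.reverse_strand)
            for x, y in zip(a, b)
        )

    def test_mean_coverage_near_nominal(self):
        ref = simulate_reference(4000, seed=8)
        reads = simulate_reads(ref, [], coverage=80, read_len=100, seed=8)
        total = sum(len(r.bases) for r in reads)
        assert abs(total / ref.length - 80) / 80 < 0.05

    def test_spiked_alt_fraction_concentrates(self):
        ref = simulate_reference(4000, seed=9)
        pos = 2000
        alt = "ACGT"[("ACGT".index(ref.base(pos)) + 1) % 4]
        truth = [TruthVariant(pos=pos, ref=ref.base(pos), alt=alt, type="SNV", target_vaf=0.5)]
        reads = simulate_reads(ref, truth, coverage=2000, read_len=100, seed=9)
        pp = build_pileup(reads, ref)
        col = pp.column(pos)
        frac = col.base_counts()["ACGT".index(alt)] / col.depth
        assert abs(frac - 0.5) < 0.03

    def test_read_len_longer_than_reference_rejected(self):
        ref = simulate_reference(100, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(ref, [], coverage=10, read_len=200, seed=1)

    def test_called_vaf_regresses_on_target_vaf(self):
        # spiked VAF recovery: slope of called-on-target within [0.9, 1.1]
        ref = simulate_reference(16569, seed=10)
        truth = [v for v in spike_variants(ref, 30, 0, seed=10, vaf_range=(0.05, 0.5))]
        reads = simulate_reads(ref, truth, coverage=2000, seed=10)
        pp = build_pileup(reads, ref)
        by_key = {c.key: c for c in call_snvs(pp)}
        xs, ys = [], []
        for v in truth:
            assert v.key in by_key
            xs.append(v.target_vaf)
            ys.append(by_key[v.key].vaf)
        slope = np.polyfit(xs, ys, 1)[0]
        assert 0.9 <= slope <= 1.1


def _call(pos, ref, alt):
    from mitovar import classify_alleles

    return VariantCall(
        pos=pos, ref=ref, alt=alt, type=classify_alleles(ref, alt),
        vaf=0.1, depth=100, strand_counts=(5, 5),
    )


class TestEvaluate:
    def _truth(self):
        return [
            TruthVariant(pos=10, ref="A", alt="G", type="SNV", target_vaf=0.1),
            TruthVariant(pos=20, ref="C", alt="T", type="SNV", target_vaf=0.2),
            TruthVariant(pos=30, ref="GA", alt="G", type="DEL", target_vaf=0.3),
        ]

    def test_perfect_calls(self):
        truth = self._truth()
        calls = [_call(v.pos, v.ref, v.alt) for v in truth]
        res = evaluate_calls(calls, truth)
        assert (res.overall.tp, res.overall.fp, res.overall.fn) == (3, 0, 0)
        assert res.overall.all_sites == 3

    def test_empty_calls_all_false_negative(self):
        res = evaluate_calls([], self._truth())
        assert res.overall.fn == 3
        assert res.snv.fn == 2 and res.indel.fn == 1

    def test_snv_only_caller_misses_every_indel(self):
        ref = simulate_reference(16569, seed=12)
        truth = spike_variants(ref, 35, 8, seed=12)
        snv_calls = [_call(v.pos, v.ref, v.alt) for v in truth if v.type == "SNV"]
        res = evaluate_calls(snv_calls, truth)
        assert res.indel.fn == 8
        assert res.snv.tp == 35

    def test_allele_mismatch_counts_both_ways(self):
        truth = self._truth()
        res = evaluate_calls([_call(10, "A", "T")], truth)  # wrong alt
        assert res.overall.fp == 1
        assert res.overall.fn == 3
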