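"""Bayesian genotype posterior and SNV call gating."""

import math

import numpy as np
import pytest

from mitovar import (
    CallerParams,
    GenotypeHypothesis,
    PriorTable,
    build_pileup,
    call_snvs,
    log_likelihood,
    phred_to_error,
    posterior_genotypes,
    simulate_reads,
    simulate_reference,
)

from conftest import make_read


class TestPhred:
    @pytest.mark.parametrize(
        "q, expected",
        [(30, 0.001), (10, 0.1), (20, 0.01), (0, 0.75), (90, 1e-6)],
    )
    def test_error_probabilities(self, q, expected):
        assert phred_to_error(q) == pytest.approx(expected, rel=1e-12)

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            phred_to_error(-1)


def _column(ref16, obs, pos=1):
    """Pileup column from (base, qual, strand) observations at ``pos``."""
    reads = [
        make_read(pos, b, qual=q, name=f"r{i}", reverse=bool(s))
        for i, (b, q, s) in enumerate(obs)
    ]
    pp = build_pileup(reads, ref16, min_baseq=0, min_mapq=0)
    return pp.column(pos)


class TestLikelihood:
    def test_homozygous_match_and_mismatch(self, ref16):
        col = _column(ref16, [("A", 30, 0), ("A", 30, 1)])
        ll_match = log_likelihood(col, GenotypeHypothesis("HOM", "A"))
        assert ll_match == pytest.approx(2 * math.log(0.999), rel=1e-12)
        ll_mis = log_likelihood(col, GenotypeHypothesis("HOM", "C"))
        assert ll_mis == pytest.approx(2 * math.log(0.001 / 3), rel=1e-12)

    def test_balanced_het_beats_both_homs(self, ref16):
        col = _column(ref16, [("A", 30, 0), ("G", 30, 1)])
        het = log_likelihood(col, GenotypeHypothesis("HET", "A", "G", 0.5))
        assert het > log_likelihood(col, GenotypeHypothesis("HOM", "A"))
        assert het > log_likelihood(col, GenotypeHypothesis("HOM", "G"))
        # direct evaluation oracle: each obs has P = 0.5*(1-e) + 0.5*e/3
        expected = 2 * math.log(0.5 * 0.999 + 0.5 * 0.001 / 3)
        assert het == pytest.approx(expected, rel=1e-12)


class TestPosterior:
    def test_no_data_returns_prior(self, ref16):
        col = _column(ref16, [])
        post = posterior_genotypes(col, PriorTable())
        assert len(post) == 4
        for p in post.values():
            assert p == pytest.approx(0.25)

    def test_unanimous_column_is_confident_hom(self, ref16):
        col = _column(ref16, [("A", 30, i % 2) for i in range(100)])
        post = posterior_genotypes(col)
        best = max(post, key=post.get)
        assert best == GenotypeHypothesis("HOM", "A")
        assert post[best] > 0.999

    def test_five_percent_minor_selects_het(self, ref16):
        obs = [("A", 30, i % 2) for i in range(95)] + [("G", 30, i % 2) for i in range(5)]
        post = posterior_genotypes(_column(ref16, obs))
        best = max(post, key=post.get)
        assert best.kind == "HET"
        assert (best.major, best.minor) == ("A", "G")
        assert best.f == pytest.approx(0.05)

    def test_posteriors_sum_to_one(self, ref16):
        for obs in (
            [("A", 30, 0)] * 3,
            [("A", 30, 0), ("G", 25, 1), ("T", 12, 0)],
            [("C", 5, 1)] * 7 + [("T", 38, 0)] * 2,
        ):
            post = posterior_genotypes(_column(ref16, obs))
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)


class TestCallGates:
    def test_one_percent_minor_below_floor_not_called(self, ref16):
        # ref at pos 1 is A; 99 A + 1 G: below the 2% heteroplasmy floor
        reads = [make_read(1, "A", name=f"a{i}", reverse=i % 2 == 0) for i in range(99)]
        reads += [make_read(1, "G", name="g0")]
        pp = build_pileup(reads, ref16)
        assert call_snvs(pp) == []

    def test_homoplasmic_nonreference_called_with_vaf_one(self, ref16):
        reads = [make_read(1, "G", name=f"g{i}", reverse=i % 2 == 0) for i in range(100)]
        pp = build_pileup(reads, ref16)
        calls = call_snvs(pp)
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos, c.ref, c.alt, c.vaf, c.genotype) == (1, "A", "G", 1.0, "1/1")

    def test_strand_confined_minor_not_called(self, ref16):
        # 5% minor but all alt reads on the forward strand
        reads = [make_read(1, "A", name=f"a{i}", reverse=i % 2 == 0) for i in range(95)]
        reads += [make_read(1, "G", name=f"g{i}", reverse=False) for i in range(5)]
        pp = build_pileup(reads, ref16)
        assert call_snvs(pp) == []

    def test_balanced_minor_called_with_empirical_vaf(self, ref16):
        reads = [make_read(1, "A", name=f"a{i}", reverse=i % 2 == 0) for i in range(95)]
        reads += [make_read(1, "G", name=f"g{i}", reverse=i % 2 == 0) for i in range(5)]
        pp = build_pileup(reads, ref16)
        calls = call_snvs(pp)
        assert len(calls) == 1
        c = calls[0]
        assert (c.ref, c.alt, c.genotype) == ("A", "G", "0/1")
        assert c.vaf == pytest.approx(0.05)
        assert c.strand_counts == (2, 3)  # g1, g3 forward; g0, g2, g4 reverse

    def test_min_depth_gate(self, ref16):
        reads = [make_read(1, "G", name=f"g{i}") for i in range(5)]
        pp = build_pileup(reads, ref16)
        assert call_snvs(pp, params=CallerParams(min_depth=10)) == []
        assert len(call_snvs(pp, params=CallerParams(min_depth=5))) == 1

    def test_raising_min_vaf_never_increases_calls(self):
        ref = simulate_reference(2000, seed=21)
        from mitovar import spike_variants

        truth = spike_variants(ref, 12, 0, seed=21, vaf_range=(0.01, 0.3))
        reads = simulate_reads(ref, truth, coverage=400, read_len=100, seed=21)
        pp = build_pileup(reads, ref)
        n_prev = None
        for min_vaf in (0.01, 0.02, 0.05, 0.1, 0.5):
            n = len(call_snvs(pp, params=CallerParams(min_vaf=min_vaf)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_noiseless_reference_reads_yield_no_calls(self):
        ref = simulate_reference(1500, seed=4)
        reads = simulate_reads(ref, [], coverage=60, read_len=100, sequencing_errors=False, seed=4)
        pp = build_pileup(reads, ref)
        assert call_snvs(pp) == []


class TestPriors:
    def test_tsv_floor_and_renormalization(self, tmp_path):
        p = tmp_path / "priors.tsv"
        p.write_text("pos\tA\tC\tG\tT\n42\t0.0\t0.5\t0.5\t0.0\n")
        pt = PriorTable.from_tsv(p)
        freqs = pt.freqs(42)
        assert freqs.sum() == pytest.approx(1.0)
        assert freqs.min() > 0  # zeros floored
        assert np.allclose(pt.freqs(99), 0.25)  # absent position -> uniform

    def test_packaged_example_priors_load(self):
        from importlib import resources

        path = resources.files("mitovar") / "data" / "example_priors.tsv"
        pt = PriorTable.from_tsv(str(path))
        assert pt.freqs(73).sum() == pytest.approx(1.0)

    def test_informative_prior_shifts_weak_posterior(self, ref16):
        # one low-quality observation: prior should dominate
        col = _column(ref16, [("A", 5, 0)])
        skewed = PriorTable({1: np.array([0.01, 0.01, 0.97, 0.01])})
        post = posterior_genotypes(col, skewed)
        best = max(post, key=post.get)
        assert best == GenotypeHypothesis("HOM", "G")
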