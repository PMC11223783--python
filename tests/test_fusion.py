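"""Normalization, multiallelic splitting and the SNV+indel fusion merge."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from mitovar import (
    Reference,
    VariantCall,
    VcfRecord,
    merge_fusion,
    normalize_variant,
    split_multiallelic,
)
from mitovar.fusion import normalize_alleles


# --- independent enumeration oracle ---------------------------------------

def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def enumerate_representations(seq: str, alt_seq: str, max_allele: int = 12):
    """All (pos, ref, alt) VCF representations turning seq into alt_seq."""
    delta = len(alt_seq) - len(seq)
    reps = []
    for pos in range(1, len(seq) + 1):
        if seq[: pos - 1] != alt_seq[: pos - 1]:
            break
        for rl in range(1, max_allele + 1):
            al = rl + delta
            if al < 1 or pos - 1 + rl > len(seq):
                continue
            a = alt_seq[pos - 1 : pos - 1 + al]
            r = seq[pos - 1 : pos - 1 + rl]
            if r == a:
                continue
            if seq[pos - 1 + rl :] == alt_seq[pos - 1 + al :]:
                reps.append((pos, r, a))
    return reps


def oracle_canonical(seq: str, alt_seq: str):
    """Left-most among the most parsimonious representations."""
    reps = enumerate_representations(seq, alt_seq)
    assert reps
    best_len = min(len(r) + len(a) for _, r, a in reps)
    return min((p, r, a) for p, r, a in reps if len(r) + len(a) == best_len)


# ---------------------------------------------------------------------------


class TestNormalize:
    def test_deletion_in_homopolymer_left_aligned(self):
        ref = Reference("chrM", "ATTTTC")
        rec = VcfRecord(chrom="chrM", pos=4, ref="TT", alts=["T"])
        out = normalize_variant(rec, ref)
        assert (out.pos, out.ref, out.alts) == (1, "AT", ["A"])
        # agrees with the enumeration oracle
        assert oracle_canonical(ref.sequence, apply_variant(ref.sequence, 4, "TT", "T")) == (
            1,
            "AT",
            "A",
        )

    def test_snv_passes_through(self):
        ref = Reference("chrM", "ATTTTC")
        rec = VcfRecord(chrom="chrM", pos=3, ref="T", alts=["G"])
        out = normalize_variant(rec, ref)
        assert (out.pos, out.ref, out.alts) == (3, "T", ["G"])

    def test_shared_context_trims_to_snv(self):
        ref = Reference("chrM", "AACGTT")
        rec = VcfRecord(chrom="chrM", pos=2, ref="AC", alts=["GC"])
        out = normalize_variant(rec, ref)
        assert (out.pos, out.ref, out.alts) == (2, "A", ["G"])

    def test_left_extension_past_start_rejected(self):
        ref = Reference("chrM", "TTTTC")
        rec = VcfRecord(chrom="chrM", pos=1, ref="TT", alts=["T"])
        with pytest.raises(ValueError, match="contig start"):
            normalize_variant(rec, ref)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_enumeration_oracle_on_random_indels(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        # low-entropy runs make harder left-alignment cases
        if seed % 2:
            seq = seq[:10] + "T" * 6 + seq[16:]
        ref = Reference("chrM", seq)
        pos = int(rng.integers(5, 30))
        if rng.random() < 0.5:
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=rng.integers(1, 4)))
            raw = (pos, seq[pos - 1], seq[pos - 1] + ins)
        else:
            dlen = int(rng.integers(1, 4))
            raw = (pos, seq[pos - 1 : pos + dlen], seq[pos - 1])
        alt_seq = apply_variant(seq, *raw)
        expected = oracle_canonical(seq, alt_seq)
        # normalize every equivalent representation to the same canonical form
        for rep in enumerate_representations(seq, alt_seq, max_allele=6):
            assert normalize_alleles(*rep, ref) == expected

    @given(pos=st.integers(2, 28), dlen=st.integers(1, 4), seed=st.integers(0, 50))
    @settings(max_examples=60, deadline=None)
    def test_idempotence(self, pos, dlen, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=36))
        ref = Reference("chrM", seq)
        raw = (pos, seq[pos - 1 : pos - 1 + dlen + 1], seq[pos - 1])
        try:
            once = normalize_alleles(*raw, ref)
        except ValueError:
            # left-aligns past the contig start: not representable in VCF
            assume(False)
        assert normalize_alleles(*once, ref) == once


class TestSplit:
    def test_biallelic_identity(self):
        rec = VcfRecord(chrom="chrM", pos=7, ref="A", alts=["G"])
        assert split_multiallelic(rec) == [rec]

    def test_two_snv_alts_split_with_per_allele_af(self):
        rec = VcfRecord(
            chrom="chrM",
            pos=7,
            ref="A",
            alts=["G", "T"],
            sample_fields={"GT": "1/2", "AF": [0.6, 0.3], "DP": 100},
        )
        out = split_multiallelic(rec)
        assert [(r.ref, r.alts[0]) for r in out] == [("A", "G"), ("A", "T")]
        assert [r.sample_fields["AF"] for r in out] == [0.6, 0.3]
        assert all(r.sample_fields["DP"] == 100 for r in out)

    def test_mixed_snv_and_insertion_types(self):
        rec = VcfRecord(chrom="chrM", pos=7, ref="A", alts=["G", "AT"])
        out = split_multiallelic(rec)
        from mitovar import classify_alleles

        assert [classify_alleles(r.ref, r.alts[0]) for r in out] == ["SNV", "INS"]


def _call(pos, ref, alt, source="x"):
    from mitovar import classify_alleles

    return VariantCall(
        pos=pos, ref=ref, alt=alt, type=classify_alleles(ref, alt),
        vaf=0.1, depth=100, strand_counts=(5, 5), source=source,
    )


class TestMerge:
    def test_indel_wins_positional_conflict(self):
        snv = _call(100, "A", "G", "bayes-snv")
        dele = _call(100, "AT", "A", "indel-standin")
        out = merge_fusion([snv], [dele])
        assert [c.key for c in out] == [(100, "AT", "A")]

    def test_non_conflicting_snv_kept(self):
        out = merge_fusion([_call(200, "A", "G")], [_call(100, "AT", "A")])
        assert [c.pos for c in out] == [100, 200]

    def test_snv_from_indel_caller_dropped(self):
        out = merge_fusion([], [_call(300, "A", "G", "indel-standin")])
        assert out == []

    def test_empty_indel_set_is_identity_on_snvs(self):
        snvs = [_call(10, "A", "G"), _call(20, "C", "T")]
        assert merge_fusion(snvs, []) == snvs

    def test_output_unique_and_bounded(self):
        snvs = [_call(10, "A", "G"), _call(10, "A", "G")]
        indels = [_call(15, "AT", "A"), _call(15, "AT", "A")]
        out = merge_fusion(snvs, indels)
        assert len(out) == 2
        assert len({c.key for c in out}) == len(out)

    def test_unnormalized_input_rejected(self):
        bad = _call(50, "ATT", "AT")  # shared leading and trailing base
        with pytest.raises(ValueError, match="unnormalized"):
            merge_fusion([], [bad])
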