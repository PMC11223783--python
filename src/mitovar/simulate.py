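"""Synthetic references, truth sets and reads for benchmarking the callers.

The simulator regenerates a gold-standard experiment entirely in memory:
a random mitochondrial-sized reference, a per-sample truth set of
heteroplasmic SNVs and short indels at chosen allele fractions, and
uniformly placed single-end reads carrying each overlapping variant
independently with probability equal to its target VAF.  Sequencing
errors are injected per base at the Phred-implied rate.  Everything is
driven by one seed: the same seed reproduces the dataset, and therefore
the entire downstream evaluation, exactly.

Reads are emitted pre-aligned (position + CIGAR assigned at
construction), matching the toolkit's expectation of aligned input;
indels are realized directly in the read sequence and CIGAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fusion import normalize_alleles
from .io_formats import AlignedRead, Reference
from .snv import phred_to_error
from .variants import classify_alleles

__all__ = [
    "TruthVariant",
    "SimulationSpec",
    "EvalCounts",
    "simulate_reference",
    "spike_variants",
    "simulate_reads",
    "evaluate_calls",
]

_BASES = "ACGT"
MT_LENGTH = 16569  # human mitochondrial genome length


@dataclass(frozen=True)
class TruthVariant:
    """A spiked variant in normalized (left-aligned, parsimonious) form."""

    pos: int
    ref: str
    alt: str
    type: str  # SNV | INS | DEL
    target_vaf: float

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


@dataclass
class SimulationSpec:
    """Study conditions for one simulated benchmark run.

    Defaults regenerate the gold-standard design: 30 samples on a
    16,569 bp contig, each carrying 35 heteroplasmic SNVs and 8
    heteroplasmic 1-5 bp indels at VAFs uniform on [0.02, 0.5], read at
    2000x with 150 bp single-end Q30 reads and Phred-driven errors.
    """

    ref_length: int = MT_LENGTH
    n_samples: int = 30
    n_snvs: int = 35
    n_indels: int = 8
    vaf_range: tuple[float, float] = (0.02, 0.5)
    coverage: float = 2000.0
    read_len: int = 150
    base_qual: int = 30
    sequencing_errors: bool = True
    min_spacing: int = 10
    max_indel_len: int = 5
    seed: int = 0


def simulate_reference(length: int = MT_LENGTH, seed: int = 0) -> Reference:
    """Uniform random ACGT contig of the given length, fully seeded."""
    if length <= 0:
        raise ValueError("reference length must be positive")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    seq = "".join(_BASES[c] for c in codes)
    return Reference(name="chrM", sequence=seq)


def spike_variants(
    reference: Reference,
    n_snvs: int,
    n_indels: int,
    seed: int = 0,
    vaf_range: tuple[float, float] = (0.02, 0.5),
    min_spacing: int = 10,
    max_indel_len: int = 5,
) -> list[TruthVariant]:
    """Draw a truth set of heteroplasmic SNVs and indels.

    Positions keep a minimum spacing so events never overlap; every
    record is emitted in normalized form (left-aligned parsimonious
    representation), so the truth set is a fixpoint of normalization.
    """
    rng = np.random.default_rng(seed)
    L = reference.length
    n_total = n_snvs + n_indels
    margin = max_indel_len + min_spacing
    lo, hi = margin + 1, L - margin
    if hi - lo + 1 < n_total * min_spacing:
        raise ValueError("reference too short for the requested variant count/spacing")

    candidates = rng.permutation(np.arange(lo, hi + 1))
    seq = reference.sequence

    is_indel = np.zeros(n_total, dtype=bool)
    is_indel[:n_indels] = True
    rng.shuffle(is_indel)

    chosen: list[TruthVariant] = []
    occupied: list[int] = []
    ci = 0
    for want_indel in is_indel:
        placed = False
        while ci < len(candidates):
            pos = int(candidates[ci])
            ci += 1
            if any(abs(pos - q) < min_spacing + max_indel_len for q in occupied):
                continue
            vaf = float(rng.uniform(*vaf_range))
            ref_base = seq[pos - 1]
            if not want_indel:
                alt = _BASES[
                    (int(_BASES.index(ref_base)) + int(rng.integers(1, 4))) % 4
                ]
                npos, nref, nalt = pos, ref_base, alt
            else:
                length = int(rng.integers(1, max_indel_len + 1))
                if rng.random() < 0.5:  # insertion after the anchor
                    ins = "".join(_BASES[c] for c in rng.integers(0, 4, size=length))
                    raw = (pos, ref_base, ref_base + ins)
                else:  # deletion of the bases after the anchor
                    raw = (pos, seq[pos - 1 : pos + length], ref_base)
                npos, nref, nalt = normalize_alleles(*raw, reference)
            if any(abs(npos - q) < min_spacing for q in occupied):
                continue
            chosen.append(
                TruthVariant(
                    pos=npos,
                    ref=nref,
                    alt=nalt,
                    type=classify_alleles(nref, nalt),
                    target_vaf=vaf,
                )
            )
            occupied.append(npos)
            placed = True
            break
        if not placed:
            raise ValueError("could not place all variants with the required spacing")
    chosen.sort(key=lambda v: v.pos)
    return chosen


def _realize_read(
    start: int,
    read_len: int,
    seq: str,
    L: int,
    carried: list[TruthVariant],
) -> tuple[str, str]:
    """Build (bases, cigar) for a read drawn from the alt haplotype."""
    chunks: list[str] = []
    nb = 0  # bases collected so far
    ops: list[tuple[str, int]] = []

    def add(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    pos = start
    vi = 0
    carried = sorted(carried, key=lambda v: v.pos)
    while nb < read_len and pos <= L:
        while vi < len(carried) and carried[vi].pos < pos:
            vi += 1
        if vi < len(carried) and carried[vi].pos == pos:
            v = carried[vi]
            vi += 1
            if v.type == "SNV":
                chunks.append(v.alt)
                nb += 1
                add("M", 1)
                pos += 1
                continue
            # anchor base
            chunks.append(seq[pos - 1])
            nb += 1
            add("M", 1)
            if v.type == "INS":
                ins = v.alt[1:]
                k = min(len(ins), read_len - nb)
                if k > 0:
                    chunks.append(ins[:k])
                    nb += k
                    add("I", k)
                pos += 1
            else:  # DEL
                dlen = len(v.ref) - 1
                if nb < read_len and pos + dlen <= L:
                    add("D", dlen)
                pos += 1 + dlen
        else:
            nxt = carried[vi].pos if vi < len(carried) else L + 1
            k = min(read_len - nb, nxt - pos, L - pos + 1)
            chunks.append(seq[pos - 1 : pos - 1 + k])
            nb += k
            add("M", k)
            pos += k
    # drop a trailing deletion: nothing after it was sequenced
    if ops and ops[-1][0] == "D":
        ops.pop()
    return "".join(chunks), "".join(f"{n}{op}" for op, n in ops)


def simulate_reads(
    reference: Reference,
    truth: list[TruthVariant],
    coverage: float,
    read_len: int = 150,
    base_qual: int = 30,
    sequencing_errors: bool = True,
    seed: int = 0,
    name_prefix: str = "r",
) -> list[AlignedRead]:
    """Simulate uniformly placed single-end reads over the reference.

    Each read carries every truth variant overlapping its span
    independently with probability equal to the variant's target VAF;
    per-base errors occur with probability ``phred_to_error(base_qual)``
    and substitute uniformly among the other three bases.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = reference.length
    if read_len > L:
        raise ValueError("read length exceeds reference length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(L * coverage / read_len))
    starts = rng.integers(1, L - read_len + 2, size=n_reads)  # 1-based
    strands = rng.random(n_reads) < 0.5

    ref_codes = np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    ref_idx = lut[ref_codes]

    # carrier draws, one pass per truth variant (order fixed by position)
    carried_by_read: dict[int, list[TruthVariant]] = {}
    snv_carriers: list[tuple[TruthVariant, np.ndarray]] = []
    for v in truth:
        overlap = np.nonzero((starts <= v.pos) & (v.pos <= starts + read_len - 1))[0]
        if overlap.size == 0:
            continue
        carry = overlap[rng.random(overlap.size) < v.target_vaf]
        if v.type == "SNV":
            snv_carriers.append((v, carry))
        else:
            for ridx in carry.tolist():
                carried_by_read.setdefault(ridx, []).append(v)
    complex_idx = set(carried_by_read)
    # SNVs on indel-carrying reads are realized in the per-read walk
    for v, carry in snv_carriers:
        for ridx in carry.tolist():
            if ridx in complex_idx:
                carried_by_read[ridx].append(v)

    # vectorized simple reads: pure-match CIGAR, substitution spikes + errors
    codes = ref_idx[(starts - 1)[:, None] + np.arange(read_len)[None, :]].copy()
    for v, carry in snv_carriers:
        simple_carry = np.array(
            [r for r in carry.tolist() if r not in complex_idx], dtype=np.int64
        )
        if simple_carry.size:
            codes[simple_carry, v.pos - starts[simple_carry]] = lut[ord(v.alt)]

    err_p = phred_to_error(base_qual) if sequencing_errors else 0.0
    if err_p > 0:
        total = codes.size
        n_err = rng.binomial(total, err_p)
        if n_err:
            # with-replacement draw: at ~1e-3 error rate the chance of
            # hitting the same base twice is negligible at this scale
            flat_pos = rng.integers(0, total, size=n_err)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            codes.reshape(-1)[flat_pos] = (codes.reshape(-1)[flat_pos] + shift) % 4
    base_arr = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)

    quals_template = np.full(read_len, base_qual, dtype=np.uint8)
    cigar_simple = f"{read_len}M"
    seq_str = reference.sequence
    reads: list[AlignedRead] = []
    simple_strings = (
        base_arr[codes].reshape(n_reads * read_len).tobytes().decode("ascii")
    )
    for i in range(n_reads):
        name = f"{name_prefix}{i}"
        if i in complex_idx:
            bases, cigar = _realize_read(
                int(starts[i]), read_len, seq_str, L, carried_by_read[i]
            )
            if err_p > 0 and bases:
                bl = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
                bcodes = lut[bl].copy()
                mask = np.nonzero(rng.random(bcodes.size) < err_p)[0]
                if mask.size:
                    bcodes[mask] = (
                        bcodes[mask] + rng.integers(1, 4, size=mask.size).astype(np.uint8)
                    ) % 4
                    bases = base_arr[bcodes].tobytes().decode("ascii")
            quals = np.full(len(bases), base_qual, dtype=np.uint8)
        else:
            bases = simple_strings[i * read_len : (i + 1) * read_len]
            cigar = cigar_simple
            quals = quals_template
        reads.append(
            AlignedRead(
                name=name,
                pos=int(starts[i]),
                cigar=cigar,
                bases=bases,
                quals=quals,
                mapq=60,
                reverse_strand=bool(strands[i]),
            )
        )
    return reads


@dataclass
class EvalCounts:
    """TP/FP/FN accounting against a truth set, overall and per type."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def all_sites(self) -> int:
        """Identified sites: true plus false positives."""
        return self.tp + self.fp


@dataclass
class EvalResult:
    overall: EvalCounts = field(default_factory=EvalCounts)
    snv: EvalCounts = field(default_factory=EvalCounts)
    indel: EvalCounts = field(default_factory=EvalCounts)

    def as_dict(self) -> dict:
        return {
            cat: {
                "all_sites": c.all_sites,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
            }
            for cat, c in (("all", self.overall), ("snv", self.snv), ("indel", self.indel))
        }


def evaluate_calls(calls, truth: list[TruthVariant]) -> EvalResult:
    """Match calls to truth on exact normalized (pos, ref, alt) keys."""
    call_keys = {c.key if hasattr(c, "key") else tuple(c) for c in calls}
    truth_keys = {v.key for v in truth}

    def _cat(key) -> str:
        _, ref, alt = key
        return "snv" if classify_alleles(ref, alt) == "SNV" else "indel"

    res = EvalResult()
    for key in call_keys:
        buckets = (res.overall, res.snv if _cat(key) == "snv" else res.indel)
        if key in truth_keys:
            for b in buckets:
                b.tp += 1
        else:
            for b in buckets:
                b.fp += 1
    for key in truth_keys:
        if key not in call_keys:
            for b in (res.overall, res.snv if _cat(key) == "snv" else res.indel):
                b.fn += 1
    return res
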