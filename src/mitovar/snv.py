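"""Bayesian per-position SNV and heteroplasmy caller.

At every pileup column the caller scores homoplasmic hypotheses HOM(X)
for the four bases and heteroplasmic hypotheses HET(major, minor, f) for
every pair of observed bases, with the minor fraction f fixed at its
empirical estimate.  The likelihood comes from the per-base Phred
qualities:

    P(b | HOM X)        = 1 - e      if b == X, else e / 3
    P(b | HET M, m, f)  = (1 - f) P(b | HOM M) + f P(b | HOM m)

with e the Phred error probability of the observation.  The prior puts
mass ``1 - theta_het`` on the homoplasmic hypotheses, apportioned by a
per-position population allele-frequency table (uniform when no table is
supplied), and ``theta_het`` spread evenly over the candidate
heteroplasmies.  The maximum-posterior hypothesis is selected and turned
into a homoplasmic or heteroplasmic call; heteroplasmies must clear a
minimum minor-allele level (2% by default) and carry minor support on
both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import Reference
from .pileup import BASES, Pileup, PileupColumn, base_code
from .variants import VariantCall

__all__ = [
    "PriorTable",
    "GenotypeHypothesis",
    "CallerParams",
    "phred_to_error",
    "log_likelihood",
    "posterior_genotypes",
    "call_snvs",
]

_ERROR_FLOOR = 1e-6
_ERROR_CEIL = 0.75
_FREQ_FLOOR = 1e-4


def phred_to_error(q: float) -> float:
    """Phred score -> error probability, clamped to [1e-6, 0.75]."""
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return min(max(10.0 ** (-q / 10.0), _ERROR_FLOOR), _ERROR_CEIL)


@dataclass(frozen=True)
class GenotypeHypothesis:
    kind: str  # "HOM" or "HET"
    major: str
    minor: str | None = None
    f: float = 0.0  # minor fraction, HET only

    def __post_init__(self) -> None:
        if self.kind == "HET":
            if self.minor is None or self.minor == self.major:
                raise ValueError("HET requires distinct major/minor")
            if not 0.0 < self.f < 1.0:
                raise ValueError("HET minor fraction must be in (0, 1)")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        if self.kind == "HOM":
            return f"HOM({self.major})"
        return f"HET({self.major},{self.minor},f={self.f:.4g})"


class PriorTable:
    """Per-position population base frequencies plus heteroplasmy prior mass.

    Positions absent from the table get the uniform default 0.25 per
    base.  Loaded frequencies are floored at 1e-4 and renormalized so
    each position sums to one.
    """

    def __init__(
        self,
        table: Mapping[int, np.ndarray] | None = None,
        theta_het: float = 0.01,
    ) -> None:
        if not 0.0 < theta_het < 1.0:
            raise ValueError("theta_het must be in (0, 1)")
        self.theta_het = theta_het
        self._table: dict[int, np.ndarray] = {}
        if table:
            for pos, freqs in table.items():
                self._table[int(pos)] = self._clean(np.asarray(freqs, dtype=float))
        self._uniform = np.full(4, 0.25)

    @staticmethod
    def _clean(freqs: np.ndarray) -> np.ndarray:
        if freqs.shape != (4,) or (freqs < 0).any():
            raise ValueError("prior frequencies must be 4 non-negative values")
        freqs = np.maximum(freqs, _FREQ_FLOOR)
        return freqs / freqs.sum()

    def freqs(self, pos: int) -> np.ndarray:
        """Frequencies over (A, C, G, T) at 1-based ``pos``."""
        return self._table.get(pos, self._uniform)

    @classmethod
    def from_tsv(cls, path, theta_het: float = 0.01) -> "PriorTable":
        """Load a TSV with columns pos, A, C, G, T (header optional)."""
        table: dict[int, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in {"pos", "position"}:
                    continue
                pos = int(parts[0])
                table[pos] = np.array([float(x) for x in parts[1:5]])
        return cls(table, theta_het=theta_het)


@dataclass
class CallerParams:
    """Gates applied when turning posteriors into calls."""

    min_vaf: float = 0.02  # default heteroplasmy detection level
    min_minor_per_strand: int = 2
    min_depth: int = 10


def _class_log_probs(classes) -> list[tuple[int, int, float, float]]:
    """Per (base, qual) class: (code, count, log(1-e), log(e/3))."""
    out = []
    for b, q, n in classes:
        e = phred_to_error(q)
        out.append((b, n, math.log1p(-e), math.log(e / 3.0)))
    return out


def log_likelihood(column: PileupColumn, h: GenotypeHypothesis) -> float:
    """Log-likelihood of the column's observations under hypothesis ``h``."""
    if column.depth == 0:
        raise ValueError("log_likelihood requires depth > 0")
    cls = _class_log_probs(column.classes)
    if h.kind == "HOM":
        X = base_code(h.major)
        return sum(n * (lmatch if b == X else lmis) for b, n, lmatch, lmis in cls)
    M = base_code(h.major)
    m = base_code(h.minor)
    f = h.f
    total = 0.0
    for b, n, lmatch, lmis in cls:
        pM = math.exp(lmatch) if b == M else math.exp(lmis)
        pm = math.exp(lmatch) if b == m else math.exp(lmis)
        total += n * math.log((1.0 - f) * pM + f * pm)
    return total


def _hypotheses(column: PileupColumn) -> list[GenotypeHypothesis]:
    hyps = [GenotypeHypothesis("HOM", b) for b in BASES]
    bc = column.base_counts()
    observed = [i for i in range(4) if bc[i] > 0]
    for i in range(len(observed)):
        for j in range(i + 1, len(observed)):
            a, b = observed[i], observed[j]
            # major = the better-supported base; ties broken lexicographically
            if bc[a] >= bc[b]:
                M, m = a, b
            else:
                M, m = b, a
            f = bc[m] / (bc[M] + bc[m])
            if 0.0 < f < 1.0:
                hyps.append(GenotypeHypothesis("HET", BASES[M], BASES[m], float(f)))
    return hyps


def posterior_genotypes(
    column: PileupColumn, priors: PriorTable | None = None
) -> dict[GenotypeHypothesis, float]:
    """Posterior over genotype hypotheses at one column, normalized to 1.

    With no data (depth 0) the posterior equals the prior over the four
    homoplasmic hypotheses.
    """
    priors = priors or PriorTable()
    freqs = priors.freqs(column.pos)
    if column.depth == 0:
        return {
            GenotypeHypothesis("HOM", BASES[i]): float(freqs[i] / freqs.sum())
            for i in range(4)
        }
    hyps = _hypotheses(column)
    n_het = sum(1 for h in hyps if h.kind == "HET")
    theta = priors.theta_het
    log_post = []
    for h in hyps:
        if h.kind == "HOM":
            prior = (1.0 - theta) * float(freqs[base_code(h.major)])
        else:
            prior = theta / n_het
        log_post.append(math.log(max(prior, 1e-300)) + log_likelihood(column, h))
    mx = max(log_post)
    weights = [math.exp(lp - mx) for lp in log_post]
    z = sum(weights)
    return {h: w / z for h, w in zip(hyps, weights)}


def _select(post: dict[GenotypeHypothesis, float], ref_base: str) -> GenotypeHypothesis:
    """Max-posterior hypothesis; ties toward reference, then base order."""

    def sort_key(item):
        h, p = item
        contains_ref = ref_base in (h.major, h.minor)
        return (-p, not contains_ref, h.major, h.minor or "")

    return min(post.items(), key=sort_key)[0]


def _fast_consensus(pileup: Pileup):
    """Columns whose observations are a single base need no posterior scan.

    With one observed base the heteroplasmic hypothesis set is empty and
    the maximum posterior is HOM(observed base) whenever the data term
    dominates; they are still routed through the full posterior, but the
    index lets callers skip reference-matching unanimous columns early.
    """
    bc = pileup.counts.sum(axis=1)  # (L, 4)
    n_observed = (bc > 0).sum(axis=1)
    argmax = bc.argmax(axis=1)
    return n_observed, argmax


def call_snvs(
    pileup: Pileup,
    reference: Reference | None = None,
    priors: PriorTable | None = None,
    params: CallerParams | None = None,
) -> list[VariantCall]:
    """Call homoplasmic and heteroplasmic SNVs from a pileup.

    Columns below ``min_depth`` are skipped.  A heteroplasmic selection
    is accepted only if the non-reference allele level clears ``min_vaf``
    and the minor allele has ``min_minor_per_strand`` observations on
    each strand; otherwise the column falls back to its homoplasmic
    (major-allele) interpretation.
    """
    reference = reference or pileup.reference
    priors = priors or PriorTable()
    params = params or CallerParams()
    refseq = reference.sequence
    calls: list[VariantCall] = []

    n_observed, argmax = _fast_consensus(pileup)
    ref_codes = np.frombuffer(refseq.encode("ascii"), dtype=np.uint8)
    from .pileup import _CODE  # reuse the base-code LUT

    ref_idx = _CODE[ref_codes]
    depth_ok = pileup.depth >= params.min_depth
    # unanimous reference-matching columns can never yield a call
    interesting = np.nonzero(
        depth_ok & ~((n_observed == 1) & (argmax == ref_idx))
    )[0]

    for i in interesting.tolist():
        pos = i + 1
        column = pileup.column(pos)
        ref_base = refseq[i]
        post = posterior_genotypes(column, priors)
        best = _select(post, ref_base)
        calls.extend(_column_calls(column, best, ref_base, params))
    calls.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return calls


def _column_calls(
    column: PileupColumn,
    best: GenotypeHypothesis,
    ref_base: str,
    params: CallerParams,
) -> list[VariantCall]:
    depth = column.depth

    def hom_call(base: str, vaf: float = 1.0) -> VariantCall | None:
        if base == ref_base:
            return None
        b = base_code(base)
        sc = (int(column.counts[0, b]), int(column.counts[1, b]))
        n = sum(sc)
        mbq = float(column.qual_sum[:, b].sum() / n) if n else column.mean_baseq
        return VariantCall(
            pos=column.pos,
            ref=ref_base,
            alt=base,
            type="SNV",
            vaf=vaf,
            depth=depth,
            mean_baseq=mbq,
            strand_counts=sc,
            source="bayes-snv",
            genotype="1/1",
        )

    def het_call(alt: str, level: float) -> VariantCall:
        b = base_code(alt)
        sc = (int(column.counts[0, b]), int(column.counts[1, b]))
        n = sum(sc)
        mbq = float(column.qual_sum[:, b].sum() / n) if n else column.mean_baseq
        return VariantCall(
            pos=column.pos,
            ref=ref_base,
            alt=alt,
            type="SNV",
            vaf=level,
            depth=depth,
            mean_baseq=mbq,
            strand_counts=sc,
            source="bayes-snv",
            genotype="0/1",
        )

    if best.kind == "HOM":
        c = hom_call(best.major)
        return [c] if c else []

    # heteroplasmic selection
    minor_code = base_code(best.minor)
    minor_strands = column.counts[:, minor_code]
    strands_ok = bool((minor_strands >= params.min_minor_per_strand).all())

    if best.major == ref_base:
        level = best.f  # minor (non-reference) fraction
        if level >= params.min_vaf and strands_ok:
            return [het_call(best.minor, level)]
        return []  # falls back to HOM(ref): no call
    if best.minor == ref_base:
        level = 1.0 - best.f  # non-reference (major) allele level
        if level >= params.min_vaf and strands_ok:
            return [het_call(best.major, level)]
        c = hom_call(best.major)  # fall back to HOM(major)
        return [c] if c else []
    # neither allele is the reference: major as homoplasmic-style call,
    # minor as heteroplasmy subject to the usual gates
    out = []
    c = hom_call(best.major, vaf=1.0 - best.f)
    if c:
        out.append(c)
    if best.f >= params.min_vaf and strands_ok:
        out.append(het_call(best.minor, best.f))
    return out
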