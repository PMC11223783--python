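"""Normalized biallelic variant calls shared by all callers."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["VariantCall", "classify_alleles"]


def classify_alleles(ref: str, alt: str) -> str:
    """SNV / INS / DEL by allele-length comparison (MNVs count as SNV-like)."""
    if len(ref) == len(alt):
        return "SNV"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass
class VariantCall:
    """One biallelic call: position, alleles, VAF and supporting evidence."""

    pos: int  # 1-based
    ref: str
    alt: str
    type: str  # SNV | INS | DEL
    vaf: float
    depth: int
    mean_baseq: float = 0.0
    strand_counts: tuple[int, int] = (0, 0)  # alt support (fwd, rev)
    filters: set[str] = field(default_factory=lambda: {"PASS"})
    source: str = ""
    genotype: str = "0/1"

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"VAF must be in (0, 1], got {self.vaf}")
        if self.type == "SNV" and self.ref == self.alt:
            raise ValueError("SNV alt equals ref")
        if self.depth < sum(self.strand_counts):
            raise ValueError("depth smaller than alt strand support")

    @property
    def alt_count(self) -> int:
        return sum(self.strand_counts)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)
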