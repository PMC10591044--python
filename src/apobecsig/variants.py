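"""Core somatic-variant types shared by the simulator and the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class VariantClass(str, Enum):
    SBS = "SBS"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"
    SV = "SV"


def classify_variant(ref_allele: str, alt_allele: str) -> VariantClass:
    """Classify a REF/ALT pair into SBS / INS / DEL / MNV / SV.

    Symbolic (``<DEL>``-style) and breakend (``[``/``]``) ALT alleles are
    structural variants.  Otherwise the usual VCF conventions apply:
    equal length 1 is an SBS, ALT extending REF is an insertion, REF
    extending ALT is a deletion, equal length >1 is an MNV.
    """
    if not ref_allele or not alt_allele:
        raise ValueError("empty allele")
    if alt_allele.startswith("<") or "[" in alt_allele or "]" in alt_allele:
        return VariantClass.SV
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return VariantClass.SBS
    if len(alt_allele) > len(ref_allele) and alt_allele.startswith(ref_allele):
        return VariantClass.INS
    if len(ref_allele) > len(alt_allele) and ref_allele.startswith(alt_allele):
        return VariantClass.DEL
    if len(ref_allele) == len(alt_allele):
        return VariantClass.MNV
    # Length-changing but not prefix-anchored (e.g. complex substitution):
    # treat as MNV-like complex event.
    return VariantClass.MNV


@dataclass
class SomaticVariant:
    """One tumor-vs-normal call (VCF convention: 1-based position).

    ``vaf`` is ``alt_reads/total_reads`` whenever read support is present;
    support fields are None when the caller did not provide them.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    alt_reads: int | None = None
    total_reads: int | None = None
    vaf: float | None = None
    variant_class: VariantClass | None = None
    sample_id: str = ""
    filter_status: str = "PASS"
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        if self.variant_class is None:
            self.variant_class = classify_variant(self.ref_allele, self.alt_allele)
        if self.alt_reads is not None and self.total_reads:
            if self.alt_reads > self.total_reads:
                raise ValueError("alt_reads exceeds total_reads")
            if self.vaf is None:
                self.vaf = self.alt_reads / self.total_reads

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    def indel_length(self) -> int:
        """Net inserted/deleted length (0 for substitutions)."""
        return abs(len(self.alt_allele) - len(self.ref_allele))
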