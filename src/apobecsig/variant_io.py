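"""Somatic VCF input, variant classification, and the quality filters.

The quality policy mirrors Mutect2-style post-filtering of tumor/normal
calls: a call survives only with at least 3 variant-supporting reads, at
least 10 total reads at the site, a variant allele fraction strictly over
0.05, a caller PASS (when required), and a contig outside the exclusion
set.  The enrichment-specific exclusions (C:G pairs only, no mitochondrial
calls, no C->A) live in :func:`exclude_for_enrichment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .reference import Reference
from .variants import SomaticVariant, VariantClass, classify_variant
from .spectrum import SvRecord

#: Contig names treated as mitochondrial across reference dialects.
MITOCHONDRIAL_NAMES = frozenset({"chrM", "MT", "chrMT", "M"})


class VcfFormatError(ValueError):
    """A VCF record lacks the fields this pipeline requires."""


@dataclass
class FilterPolicy:
    """Read-support and caller-status thresholds for somatic calls."""

    min_alt_reads: int = 3
    min_total_reads: int = 10
    min_vaf_exclusive: float = 0.05
    excluded_contigs: frozenset[str] = frozenset({"chrM"})
    require_caller_pass: bool = True

    def __post_init__(self):
        if self.min_alt_reads < 0 or self.min_total_reads < 0:
            raise ValueError("read thresholds must be nonnegative")
        if not (0 <= self.min_vaf_exclusive < 1):
            raise ValueError("min_vaf_exclusive must lie in [0, 1)")
        self.excluded_contigs = frozenset(self.excluded_contigs)


@dataclass
class FilterOutcome:
    kept: list[SomaticVariant]
    removed: list[tuple[SomaticVariant, tuple[str, ...]]] = field(default_factory=list)

    @property
    def removed_variants(self) -> list[SomaticVariant]:
        return [v for v, _ in self.removed]

    def removed_report(self) -> pd.DataFrame:
        rows = [
            {
                "contig": v.contig, "position": v.position, "ref": v.ref_allele,
                "alt": v.alt_allele, "sample_id": v.sample_id,
                "reasons": ",".join(reasons),
            }
            for v, reasons in self.removed
        ]
        return pd.DataFrame(rows, columns=["contig", "position", "ref", "alt",
                                           "sample_id", "reasons"])


def read_somatic_vcf(path, sample_id: str | None = None) -> list[SomaticVariant]:
    """Read tumor calls from a VCF 4.x file into SomaticVariant records.

    Multi-allelic records are split into one variant per ALT allele, with
    per-allele depths taken from the tumor sample's AD field (DP, or the AD
    sum, supplies the total).  ``sample_id`` selects the tumor column by
    name; with a single-sample VCF it defaults to that sample, and it also
    becomes the ``sample_id`` stored on each variant.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if samples:
        if sample_id and sample_id in samples:
            tumor_idx = samples.index(sample_id)
        elif len(samples) == 1:
            tumor_idx = 0
        elif sample_id:
            raise VcfFormatError(f"sample {sample_id!r} not found in {samples}")
        else:
            tumor_idx = 0
    else:
        tumor_idx = None
    label = sample_id or (samples[tumor_idx] if samples else "")

    def _format(record, field):
        try:
            return record.format(field)
        except KeyError:
            return None

    variants: list[SomaticVariant] = []
    for record in vcf:
        ad = _format(record, "AD") if samples else None
        dp = _format(record, "DP") if samples else None
        filter_status = record.FILTER or "PASS"
        for alt_i, alt in enumerate(record.ALT):
            alt_reads = total = None
            if ad is not None:
                row = ad[tumor_idx]
                if len(row) > alt_i + 1 and int(row[alt_i + 1]) >= 0:
                    alt_reads = int(row[alt_i + 1])
                    total = int(sum(x for x in row if x >= 0))
            if dp is not None and int(dp[tumor_idx][0]) >= 0:
                total = int(dp[tumor_idx][0])
            if samples and ad is None and dp is None:
                raise VcfFormatError(
                    f"record {record.CHROM}:{record.POS} carries no AD or DP "
                    "FORMAT field for the tumor sample"
                )
            if alt_reads is not None and total is not None:
                alt_reads = min(alt_reads, total)
            variants.append(
                SomaticVariant(
                    contig=record.CHROM,
                    position=record.POS,
                    ref_allele=record.REF,
                    alt_allele=alt,
                    alt_reads=alt_reads,
                    total_reads=total,
                    sample_id=label,
                    filter_status=filter_status,
                )
            )
    return variants


def read_sv_vcf(path, sample_id: str = "") -> list[SvRecord]:
    """Read Manta-style SV records (SVTYPE/END/MATEID INFO fields)."""
    from cyvcf2 import VCF

    records: list[SvRecord] = []
    for record in VCF(str(path)):
        for alt in record.ALT:
            records.append(
                SvRecord(
                    contig=record.CHROM,
                    position=record.POS,
                    record_id=record.ID or f"{record.CHROM}:{record.POS}",
                    ref=record.REF,
                    alt=alt,
                    svtype=record.INFO.get("SVTYPE") or "",
                    end=record.INFO.get("END"),
                    mate_id=record.INFO.get("MATEID"),
                    sample_id=sample_id,
                )
            )
    return records


def apply_quality_filters(
    variants: list[SomaticVariant], policy: FilterPolicy | None = None
) -> FilterOutcome:
    """Partition variants into kept and removed-with-reasons.

    Kept iff alt reads >= 3, total reads >= 10, VAF strictly over 0.05
    ("over 0.05" read literally), contig not excluded, and caller PASS when
    required.  Missing read support removes with reason ``missing_support``.
    The result is a partition: every input lands in exactly one list.
    """
    policy = policy or FilterPolicy()
    outcome = FilterOutcome(kept=[])
    for v in variants:
        reasons: list[str] = []
        if v.contig in policy.excluded_contigs:
            reasons.append("excluded_contig")
        if policy.require_caller_pass and v.filter_status not in ("PASS", "", "."):
            reasons.append("not_pass")
        if v.alt_reads is None or v.total_reads is None:
            reasons.append("missing_support")
        else:
            if v.alt_reads < policy.min_alt_reads:
                reasons.append("low_alt")
            if v.total_reads < policy.min_total_reads:
                reasons.append("low_depth")
            vaf = v.vaf if v.vaf is not None else (
                v.alt_reads / v.total_reads if v.total_reads else 0.0
            )
            if not vaf > policy.min_vaf_exclusive:
                reasons.append("low_vaf")
        if reasons:
            outcome.removed.append((v, tuple(reasons)))
        else:
            outcome.kept.append(v)
    return outcome


def exclude_for_enrichment(
    variants: list[SomaticVariant],
    reference: Reference,
    mitochondrial_names: frozenset[str] = MITOCHONDRIAL_NAMES,
) -> list[SomaticVariant]:
    """The four enrichment-score exclusions, applied after quality filtering.

    Retains single-base substitutions at C:G reference pairs, off the
    mitochondrial contig, that are not C->A (nor the reverse-strand
    equivalent G->T — strand handling downstream is pyrimidine-normalized).
    """
    kept = []
    for v in variants:
        if v.variant_class is not VariantClass.SBS:
            continue
        if v.contig in mitochondrial_names:
            continue
        ref_base = reference.base_at(v.contig, v.position).upper()
        if ref_base != v.ref_allele.upper():
            raise ValueError(
                f"reference lookup mismatch at {v.contig}:{v.position} "
                f"(genome {ref_base}, call {v.ref_allele})"
            )
        if ref_base not in ("C", "G"):
            continue
        pair = (ref_base, v.alt_allele.upper())
        if pair in (("C", "A"), ("G", "T")):
            continue
        kept.append(v)
    return kept
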