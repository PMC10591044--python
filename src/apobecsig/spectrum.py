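"""Mutation spectra: SBS-96 catalogs, indel categories, and SV tallies.

Every substitution is reported on the pyrimidine strand: calls whose
reference base is a purine are reverse-complemented so the mutated base is
C or T.  Channels follow the canonical COSMIC SBS-96 layout: substitution
major (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base, each in
alphabetical order, i.e. A[C>A]A, A[C>A]C, ... T[T>G]T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import Reference, revcomp, complement
from .variants import SomaticVariant, VariantClass

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
PYRIMIDINES = "CT"

SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CHANNEL_INDEX = {name: i for i, name in enumerate(SBS96_CHANNELS)}
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}


def channel_index(five: str, ref: str, alt: str, three: str) -> int:
    """Index of the pyrimidine-strand channel 5'[ref>alt]3' in COSMIC order."""
    return _SUB_INDEX[f"{ref}>{alt}"] * 16 + BASES.index(five) * 4 + BASES.index(three)


def channel_name(index: int) -> str:
    return SBS96_CHANNELS[index]


def parse_channel(name: str) -> tuple[str, str, str, str]:
    """Split ``T[C>T]A`` into (five, ref, alt, three)."""
    m = re.fullmatch(r"([ACGT])\[([CT])>([ACGT])\]([ACGT])", name)
    if not m:
        raise ValueError(f"malformed channel name {name!r}")
    return m.group(1), m.group(2), m.group(3), m.group(4)


class ContextError(ValueError):
    """Raised when a variant has no usable trinucleotide context."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def trinucleotide_context(variant: SomaticVariant, reference: Reference) -> int:
    """SBS-96 channel index of an SBS, pyrimidine-normalized.

    Raises :class:`ContextError` with reason ``"truncated_context"`` at a
    contig end and ``"ambiguous_context"`` when the context contains N.
    """
    if variant.variant_class is not VariantClass.SBS:
        raise ValueError("trinucleotide context is defined for SBS variants only")
    tri = reference.trinucleotide(variant.contig, variant.position)
    if tri is None:
        raise ContextError("truncated_context")
    tri = tri.upper()
    if "N" in tri or "N" in (variant.ref_allele, variant.alt_allele):
        raise ContextError("ambiguous_context")
    ref, alt = variant.ref_allele.upper(), variant.alt_allele.upper()
    if tri[1] != ref:
        raise ContextError(
            f"reference mismatch at {variant.contig}:{variant.position} "
            f"(genome {tri[1]}, call {ref})"
        )
    if ref not in PYRIMIDINES:
        tri = revcomp(tri)
        ref = complement(ref)
        alt = complement(alt)
    return channel_index(tri[0], ref, alt, tri[2])


@dataclass
class SbsCatalog:
    """Per-sample 96-channel trinucleotide substitution counts."""

    sample_id: str
    counts: np.ndarray
    n_skipped: int = 0
    skip_reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("an SBS catalog has exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            return np.zeros(96)
        return self.counts / tot

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(SBS96_CHANNELS), name=self.sample_id)


def build_sbs_catalog(
    variants: list[SomaticVariant], reference: Reference, sample_id: str = ""
) -> SbsCatalog:
    """Tally quality-filtered SBS calls into a 96-channel catalog.

    Non-SBS variants are ignored; SBS calls without a usable context
    (contig end, N in flank) are counted in ``n_skipped`` with reasons.
    An empty input yields a valid all-zero catalog.
    """
    counts = np.zeros(96)
    skipped: dict[str, int] = {}
    for v in variants:
        if v.variant_class is not VariantClass.SBS:
            continue
        try:
            counts[trinucleotide_context(v, reference)] += 1
        except ContextError as err:
            skipped[err.reason] = skipped.get(err.reason, 0) + 1
    return SbsCatalog(sample_id or (variants[0].sample_id if variants else ""),
                      counts, sum(skipped.values()), skipped)


def catalogs_to_frame(catalogs: list[SbsCatalog]) -> pd.DataFrame:
    """96 x S DataFrame (channels x samples) in COSMIC layout."""
    return pd.DataFrame({c.sample_id: c.to_series() for c in catalogs})


def write_catalog_tsv(catalogs: list[SbsCatalog], path) -> None:
    catalogs_to_frame(catalogs).to_csv(path, sep="\t", index_label="channel")


def read_catalog_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(SBS96_CHANNELS):
        raise ValueError("catalog TSV is not in canonical COSMIC SBS-96 channel order")
    return frame


# ---------------------------------------------------------------------------
# Indels
# ---------------------------------------------------------------------------

INDEL_CATEGORIES = (
    "ins_1bp_TA",
    "ins_1bp_CG",
    "del_1bp_TA",
    "del_1bp_CG",
    "indel_2bp",
    "indel_3bp",
    "indel_4bp",
    "del_2bp_MH",
    "del_3bp_MH",
    "del_4bp_MH",
    "indel_5plus",
)

#: Indels longer than this (exclusive) leave the small-indel landscape.
MAX_INDEL_BP = 200
#: Minimum identical bases between a deleted span and its 3' flank for
#: a 2-4 bp deletion to count as microhomology-mediated.
MIN_MICROHOMOLOGY_BP = 2


@dataclass
class IndelCatalog:
    sample_id: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in INDEL_CATEGORIES})
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_series(self) -> pd.Series:
        return pd.Series({c: self.counts.get(c, 0) for c in INDEL_CATEGORIES},
                         name=self.sample_id)


def left_align_indel(
    contig: str, position: int, ref: str, alt: str, reference: Reference
) -> tuple[int, str, str]:
    """Left-align an anchored VCF indel (shared leading base convention).

    VCF permits several equivalent representations of the same indel; the
    classifier normalizes to the leftmost before looking for microhomology.
    """
    if len(ref) > len(alt):  # deletion of ref[len(alt):]
        if not ref.startswith(alt):
            return position, ref, alt
        deleted = ref[len(alt):]
        anchor = position + len(alt) - 1  # 1-based position of last kept base
        while anchor > 1:
            prev = reference.base_at(contig, anchor).upper()
            if prev != deleted[-1]:
                break
            deleted = prev + deleted[:-1]
            anchor -= 1
        new_anchor_base = reference.base_at(contig, anchor).upper()
        return anchor, new_anchor_base + deleted, new_anchor_base
    if len(alt) > len(ref):  # insertion after ref
        if not alt.startswith(ref):
            return position, ref, alt
        inserted = alt[len(ref):]
        anchor = position + len(ref) - 1
        while anchor > 1:
            prev = reference.base_at(contig, anchor).upper()
            if prev != inserted[-1]:
                break
            inserted = prev + inserted[:-1]
            anchor -= 1
        new_anchor_base = reference.base_at(contig, anchor).upper()
        return anchor, new_anchor_base, new_anchor_base + inserted
    return position, ref, alt


def microhomology_length(
    contig: str, deletion_end: int, deleted: str, reference: Reference
) -> int:
    """Identical-prefix length between a deleted span and its immediate 3' flank.

    ``deletion_end`` is the 1-based position of the last deleted base.
    """
    flank = reference.fetch(contig, deletion_end, deletion_end + len(deleted)).upper()
    n = 0
    for a, b in zip(deleted, flank):
        if a != b:
            break
        n += 1
    return n


def classify_indel(variant: SomaticVariant, reference: Reference) -> str:
    """Assign an INS/DEL variant to one of the small-indel categories.

    1 bp events split by the inserted/deleted base (T/A vs C/G); 2-4 bp
    deletions whose removed sequence shares >= 2 identical leading bases
    with the sequence immediately 3' of the junction are microhomology
    deletions (MH wins over the plain 2-4 bp bins); everything of net
    length 5-200 bp is ``indel_5plus``.  Events over 200 bp are outside
    this catalog and raise ValueError.
    """
    if variant.variant_class not in (VariantClass.INS, VariantClass.DEL):
        raise ValueError("classify_indel expects an INS or DEL variant")
    length = variant.indel_length()
    if length == 0:
        raise ValueError("zero-length indel")
    if length > MAX_INDEL_BP:
        raise ValueError(f"indel of {length} bp exceeds the {MAX_INDEL_BP} bp catalog bound")

    pos, ref, alt = left_align_indel(
        variant.contig, variant.position, variant.ref_allele.upper(),
        variant.alt_allele.upper(), reference
    )
    genome_ref = reference.fetch(variant.contig, pos - 1, pos - 1 + len(ref)).upper()
    if genome_ref != ref:
        raise ValueError(
            f"reference mismatch at {variant.contig}:{pos} (genome {genome_ref!r}, call {ref!r})"
        )

    if variant.variant_class is VariantClass.DEL:
        deleted = ref[len(alt):]
        if length == 1:
            return "del_1bp_TA" if deleted in "TA" else "del_1bp_CG"
        if 2 <= length <= 4:
            end = pos + len(ref) - 1  # last deleted base, 1-based
            if microhomology_length(variant.contig, end, deleted, reference) >= MIN_MICROHOMOLOGY_BP:
                return f"del_{length}bp_MH"
            return f"indel_{length}bp"
        return "indel_5plus"
    inserted = alt[len(ref):]
    if length == 1:
        return "ins_1bp_TA" if inserted in "TA" else "ins_1bp_CG"
    if 2 <= length <= 4:
        return f"indel_{length}bp"
    return "indel_5plus"


def build_indel_catalog(
    variants: list[SomaticVariant], reference: Reference, sample_id: str = ""
) -> IndelCatalog:
    catalog = IndelCatalog(sample_id or (variants[0].sample_id if variants else ""))
    for v in variants:
        if v.variant_class not in (VariantClass.INS, VariantClass.DEL):
            continue
        if v.indel_length() > MAX_INDEL_BP:
            catalog.n_skipped += 1
            continue
        catalog.counts[classify_indel(v, reference)] += 1
    return catalog


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

SV_CATEGORIES = ("deletion_gt500", "duplication", "inversion", "translocation", "complex")

#: Deletions at or below this span (bp) are not counted as structural variants.
SV_DEL_MIN_SPAN = 500

_BND_RE = re.compile(r"^(?P<lead>[ACGTN]*)(?P<b1>[\[\]])(?P<mate>[^\[\]]+)(?P<b2>[\[\]])(?P<tail>[ACGTN]*)$")


@dataclass
class SvRecord:
    """A Manta-style structural-variant VCF record (symbolic or breakend)."""

    contig: str
    position: int
    record_id: str
    ref: str = "N"
    alt: str = "<DEL>"
    svtype: str = ""
    end: int | None = None
    mate_id: str | None = None
    sample_id: str = ""

    @property
    def span(self) -> int | None:
        if self.end is None:
            return None
        return abs(self.end - self.position)


@dataclass
class SvTally:
    sample_id: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in SV_CATEGORIES})
    n_below_deletion_threshold: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_series(self) -> pd.Series:
        s = pd.Series({c: self.counts.get(c, 0) for c in SV_CATEGORIES}, name=self.sample_id)
        s["total"] = self.total
        return s


def _bnd_orientation(alt: str) -> tuple[str, str] | None:
    """(mate locus, junction shape) for a breakend ALT; None if unparsable.

    Shapes follow the VCF bracket grammar from the lower-coordinate side:
    ``t[p[`` joins + to -, the deletion-like junction; ``]p]t`` the
    duplication-like one; ``t]p]`` / ``[p[t`` the two inverted joins.
    """
    m = _BND_RE.match(alt)
    if not m:
        return None
    lead, b1, mate, tail = m.group("lead"), m.group("b1"), m.group("mate"), m.group("tail")
    if lead and b1 == "[":
        shape = "del_like"
    elif tail and b1 == "]":
        shape = "dup_like"
    elif lead and b1 == "]":
        shape = "inv"
    else:
        shape = "inv"
    return mate, shape


def tally_structural_variants(records: list[SvRecord], sample_id: str = "") -> SvTally:
    """Count Manta-style SV records into the coarse SV categories.

    Breakend (BND) mates are deduplicated via MATEID and counted as one
    event: inter-contig pairs are translocations, intra-contig pairs are
    classified by junction orientation.  Symbolic DEL records count only
    when their span exceeds 500 bp; DUP and INV count directly; anything
    unmatched or unrecognized is ``complex``.
    """
    tally = SvTally(sample_id or (records[0].sample_id if records else ""))
    by_id = {r.record_id: r for r in records if r.record_id}
    seen: set[str] = set()
    for rec in records:
        svtype = (rec.svtype or "").upper()
        if svtype == "BND" or "[" in rec.alt or "]" in rec.alt:
            if rec.record_id in seen:
                continue
            seen.add(rec.record_id)
            mate = by_id.get(rec.mate_id) if rec.mate_id else None
            if mate is None:
                tally.warnings.append(f"dangling breakend {rec.record_id}")
                parsed = _bnd_orientation(rec.alt)
                mate_contig = parsed[0].split(":")[0] if parsed else None
            else:
                seen.add(mate.record_id)
                mate_contig = mate.contig
            if mate_contig is not None and mate_contig != rec.contig:
                tally.counts["translocation"] += 1
                continue
            parsed = _bnd_orientation(rec.alt)
            if parsed is None:
                tally.counts["complex"] += 1
            elif parsed[1] == "del_like":
                span = rec.span
                if span is None and parsed[0].count(":") == 1:
                    span = abs(int(parsed[0].split(":")[1]) - rec.position)
                if span is not None and span <= SV_DEL_MIN_SPAN:
                    tally.n_below_deletion_threshold += 1
                else:
                    tally.counts["deletion_gt500"] += 1
            elif parsed[1] == "dup_like":
                tally.counts["duplication"] += 1
            else:
                tally.counts["inversion"] += 1
        elif svtype == "DEL":
            span = rec.span
            if span is not None and span <= SV_DEL_MIN_SPAN:
                tally.n_below_deletion_threshold += 1
            else:
                tally.counts["deletion_gt500"] += 1
        elif svtype == "DUP":
            tally.counts["duplication"] += 1
        elif svtype == "INV":
            tally.counts["inversion"] += 1
        elif svtype in ("TRA", "CTX"):
            tally.counts["translocation"] += 1
        else:
            tally.counts["complex"] += 1
    return tally
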