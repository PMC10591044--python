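"""Truth-annotated synthetic tumor genomes, variant sets, and tracks.

The generator emulates the statistical structure of APOBEC3B-driven murine
tumors — SBS2-like C>T mutations at TC motifs over a flat aging background,
enrichment-correlated indel and SV loads, early-replication mutation bias,
and Mutect2-style read-support metadata — with an exact truth ledger so
every downstream stage can be tested for recovery.

Everything is driven by explicit integer seeds through
``numpy.random.default_rng``; identical seeds and parameters produce
byte-identical FASTA/VCF/bedGraph output.  The generator never emits N
bases, every planted position is unique per contig, and a mitochondrial
contig ("chrM") is always present and always receives a few mutations so
the chrM-exclusion rule is exercised on every run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .reference import InMemoryReference, complement
from .variants import SomaticVariant, VariantClass
from .spectrum import SBS96_CHANNELS, SvRecord, parse_channel
from .signatures import SignatureSet

MITO_NAME = "chrM"
DEFAULT_MITO_LENGTH = 16_000
_BASES = "ACGT"

#: The 32 pyrimidine-strand trinucleotide context classes (5', C/T, 3').
CONTEXTS: tuple[tuple[str, str, str], ...] = tuple(
    (five, pyr, three) for pyr in "CT" for five in _BASES for three in _BASES
)
_CONTEXT_ID = {ctx: i for i, ctx in enumerate(CONTEXTS)}

#: channel index -> context class index
CHANNEL_CONTEXT = tuple(
    _CONTEXT_ID[(parse_channel(name)[0], parse_channel(name)[1], parse_channel(name)[3])]
    for name in SBS96_CHANNELS
)


class SyntheticGenome(InMemoryReference):
    """An in-memory reference genome with a designated mitochondrial contig."""

    def __init__(self, contigs: list[tuple[str, str]], mito_name: str = MITO_NAME):
        names = [n for n, _ in contigs]
        if mito_name not in names:
            raise ValueError(f"genome must include the mitochondrial contig {mito_name!r}")
        if len(names) < 2:
            raise ValueError("genome needs at least one non-mitochondrial contig")
        for name, seq in contigs:
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name!r} contains bases outside A/C/G/T")
        super().__init__(contigs)
        self.mito_name = mito_name

    @property
    def nuclear_contigs(self) -> list[str]:
        return [n for n in self.contig_names() if n != self.mito_name]


def generate_genome(
    n_contigs: int,
    lengths: list[int],
    gc_fraction: float,
    seed: int,
    mito_length: int = DEFAULT_MITO_LENGTH,
) -> SyntheticGenome:
    """Sample a genome of ``n_contigs`` nuclear contigs plus chrM.

    Bases are drawn i.i.d. with P(C) = P(G) = gc/2, so the realized GC of
    any contig of at least 100 kb lies within 2 points of the request and
    trinucleotide frequencies follow the independence expectation.
    """
    if n_contigs < 1 or len(lengths) != n_contigs:
        raise ValueError("lengths must list one positive length per nuclear contig")
    if any(l <= 0 for l in lengths) or mito_length <= 0:
        raise ValueError("contig lengths must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    contigs = []
    for i, length in enumerate(lengths, start=1):
        draws = rng.choice(4, size=length, p=p)
        contigs.append((f"chr{i}", "".join(_BASES[b] for b in draws)))
    draws = rng.choice(4, size=mito_length, p=p)
    contigs.append((MITO_NAME, "".join(_BASES[b] for b in draws)))
    return SyntheticGenome(contigs)


@dataclass
class PlantedSbs:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    channel: int


@dataclass
class PlantedIndel:
    contig: str
    position: int  # 1-based VCF anchor
    ref: str
    alt: str
    category: str


@dataclass
class TruthLedger:
    """The generator's exact record of what was planted."""

    seed: int = 0
    signature_weights: dict[str, float] = field(default_factory=dict)
    planted_sbs: list[PlantedSbs] = field(default_factory=list)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    planted_sv_count: int = 0
    timing_bias: dict[int, float] = field(default_factory=dict)
    read_support_model: dict = field(default_factory=dict)
    contaminated: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.signature_weights:
            total = sum(self.signature_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("signature weights must sum to 1 (± 1e-9)")

    def indel_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for pi in self.planted_indels:
            counts[pi.category] = counts.get(pi.category, 0) + 1
        return counts

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["contaminated"] = [list(k) for k in self.contaminated]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_sbs"] = [PlantedSbs(**d) for d in payload["planted_sbs"]]
        payload["planted_indels"] = [PlantedIndel(**d) for d in payload["planted_indels"]]
        payload["timing_bias"] = {int(k): v for k, v in payload["timing_bias"].items()}
        payload["contaminated"] = [tuple(k) for k in payload["contaminated"]]
        return cls(**payload)


class ContextSiteIndex:
    """Positions of every pyrimidine-normalized trinucleotide context.

    For each contig, classifies every internal position by the context of
    its pyrimidine strand (a G-centered position is read as a C on the
    reverse strand) and stores the 0-based positions per context class.
    """

    def __init__(self, genome: SyntheticGenome):
        self.genome = genome
        code_to_ctx = np.full(64, -1, dtype=np.int8)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for code in range(64):
            tri = _BASES[code >> 4] + _BASES[(code >> 2) & 3] + _BASES[code & 3]
            if tri[1] in "CT":
                ctx = (tri[0], tri[1], tri[2])
            else:
                ctx = (comp[tri[2]], comp[tri[1]], comp[tri[0]])
            code_to_ctx[code] = _CONTEXT_ID[ctx]
        base_code = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate(_BASES):
            base_code[ord(b)] = i
        self.sites: dict[str, list[np.ndarray]] = {}
        for name in genome.contig_names():
            arr = base_code[np.frombuffer(genome.sequence(name).encode(), dtype=np.uint8)]
            codes = (arr[:-2] << 4) | (arr[1:-1] << 2) | arr[2:]
            ctx = code_to_ctx[codes]  # context of the base at 0-based index i+1
            # stored positions are 1-based (VCF convention)
            per_ctx = [np.flatnonzero(ctx == c) + 2 for c in range(32)]
            self.sites[name] = per_ctx

    def context_counts(self, contigs: list[str]) -> np.ndarray:
        counts = np.zeros(32, dtype=np.int64)
        for name in contigs:
            counts += [len(s) for s in self.sites[name]]
        return counts

    def tcw_fraction(self, contigs: list[str] | None = None) -> float:
        """Genome fraction of cytosine sites (both strands) in TCW context."""
        contigs = contigs or self.genome.nuclear_contigs
        counts = self.context_counts(contigs)
        c_total = sum(counts[_CONTEXT_ID[(f, "C", t)]] for f in _BASES for t in _BASES)
        tcw = counts[_CONTEXT_ID[("T", "C", "A")]] + counts[_CONTEXT_ID[("T", "C", "T")]]
        return tcw / c_total


def _variant_from_site(genome, contig, pos0, channel) -> PlantedSbs:
    five, pyr_ref, pyr_alt, three = parse_channel(SBS96_CHANNELS[channel])
    plus = genome.sequence(contig)[pos0]
    if plus in "CT":
        ref, alt = pyr_ref, pyr_alt
    else:
        ref, alt = plus, complement(pyr_alt)
    return PlantedSbs(contig, pos0 + 1, ref, alt, channel)


def plant_sbs_from_signatures(
    genome: SyntheticGenome,
    n_mutations: int,
    weights: dict[str, float],
    signatures: SignatureSet,
    seed: int,
    timing_track: "TimingTrack | None" = None,
    timing_bias: dict[int, float] | None = None,
    mito_mutations: int = 3,
    site_index: ContextSiteIndex | None = None,
    sample_id: str = "",
) -> tuple[list[SomaticVariant], TruthLedger]:
    """Plant single-base substitutions drawn from a signature mixture.

    Each mutation samples a 96-channel from the mixture, then a uniform
    (or timing-biased) genome position among sites matching the channel's
    pyrimidine-strand context, without replacement: a site hosts at most
    one event.  ``mito_mutations`` extra events are always planted on the
    mitochondrial contig (recorded in the ledger like any other event) so
    the chrM-exclusion rule is exercised.
    """
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    mixture = np.zeros(96)
    for name, w in weights.items():
        if w < 0:
            raise ValueError("mixture weights must be nonnegative")
        mixture += w * signatures.column(name)
    mixture = mixture / mixture.sum() if mixture.sum() else mixture
    rng = np.random.default_rng(seed)
    idx = site_index or ContextSiteIndex(genome)
    ledger = TruthLedger(seed=seed, signature_weights=dict(weights))
    if timing_bias:
        ledger.timing_bias = dict(timing_bias)

    planted: list[PlantedSbs] = []
    if n_mutations:
        channel_counts = rng.multinomial(n_mutations, mixture)
        by_context: dict[int, list[int]] = {}
        for ch, cnt in enumerate(channel_counts):
            if cnt:
                by_context.setdefault(CHANNEL_CONTEXT[ch], []).append(ch)
        for ctx_id in sorted(by_context):
            channels = by_context[ctx_id]
            need = int(sum(channel_counts[ch] for ch in channels))
            pools, weights_list = [], []
            for contig in genome.nuclear_contigs:
                sites = idx.sites[contig][ctx_id]
                if sites.size == 0:
                    continue
                if timing_track is not None and timing_bias:
                    w = timing_track.site_weights(contig, sites, timing_bias)
                else:
                    w = np.ones(sites.size)
                pools.append((contig, sites))
                weights_list.append(w)
            total_sites = sum(s.size for _, s in pools)
            if total_sites == 0:
                raise ValueError(
                    f"no eligible site for context {CONTEXTS[ctx_id]} in the genome"
                )
            if need > total_sites:
                raise ValueError(
                    f"requested {need} mutations in context {CONTEXTS[ctx_id]} "
                    f"but only {total_sites} eligible sites exist"
                )
            flat_contig = np.concatenate(
                [np.full(s.size, i) for i, (_, s) in enumerate(pools)]
            )
            flat_pos = np.concatenate([s for _, s in pools])
            flat_w = np.concatenate(weights_list).astype(float)
            if flat_w.sum() == 0:
                raise ValueError("timing bias left no eligible sites with positive weight")
            chosen = rng.choice(flat_pos.size, size=need, replace=False,
                                p=flat_w / flat_w.sum())
            rng.shuffle(chosen)
            offset = 0
            for ch in channels:
                cnt = int(channel_counts[ch])
                for j in chosen[offset:offset + cnt]:
                    contig = pools[int(flat_contig[j])][0]
                    planted.append(_variant_from_site(genome, contig, int(flat_pos[j]) - 1, ch))
                offset += cnt

    # Mitochondrial seeding: same mixture, restricted to contexts on chrM.
    mito_sites = idx.sites[genome.mito_name]
    avail = np.array([mito_sites[CHANNEL_CONTEXT[ch]].size > 0 for ch in range(96)])
    mito_mix = mixture * avail
    used_mito: set[int] = set()
    if mito_mutations and mito_mix.sum() > 0:
        mito_mix /= mito_mix.sum()
        for ch in rng.choice(96, size=mito_mutations, p=mito_mix):
            pool = [p for p in mito_sites[CHANNEL_CONTEXT[int(ch)]] if int(p) not in used_mito]
            pos = int(rng.choice(pool))
            used_mito.add(pos)
            planted.append(_variant_from_site(genome, genome.mito_name, pos - 1, int(ch)))

    planted.sort(key=lambda p: (p.contig, p.position))
    ledger.planted_sbs = planted
    variants = [
        SomaticVariant(p.contig, p.position, p.ref, p.alt,
                       variant_class=VariantClass.SBS, sample_id=sample_id)
        for p in planted
    ]
    return variants, ledger


def plant_enriched_cytosine_mutations(
    genome: SyntheticGenome,
    n_mutations: int,
    fold: float,
    seed: int,
    site_index: ContextSiteIndex | None = None,
    sample_id: str = "",
) -> list[SomaticVariant]:
    """Plant C>T mutations with TCW probability ``fold`` times background.

    With ``fold=1`` mutated cytosines are uniform over all C:G sites, the
    null of the enrichment score; with ``fold=k`` the probability that a
    mutation lands in TCW is k times the genome's TCW-per-cytosine
    fraction, so the enrichment score converges to k.
    """
    idx = site_index or ContextSiteIndex(genome)
    f = idx.tcw_fraction()
    p_tcw = fold * f
    if not 0 <= p_tcw <= 1:
        raise ValueError(f"fold {fold} gives TCW probability {p_tcw:.3f} outside [0, 1]")
    rng = np.random.default_rng(seed)
    tcw_ids = [_CONTEXT_ID[("T", "C", "A")], _CONTEXT_ID[("T", "C", "T")]]
    c_ids = [_CONTEXT_ID[(fv, "C", t)] for fv in _BASES for t in _BASES]
    other_ids = [c for c in c_ids if c not in tcw_ids]

    def gather(ids):
        contigs, positions, sizes = [], [], []
        for contig in genome.nuclear_contigs:
            for cid in ids:
                s = idx.sites[contig][cid]
                if s.size:
                    contigs.append(contig)
                    positions.append(s)
                    sizes.append(s.size)
        flat = np.concatenate(positions)
        owner = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])
        return flat, owner, contigs

    n_tcw = int(rng.binomial(n_mutations, p_tcw))
    variants: list[SomaticVariant] = []
    for ids, count in ((tcw_ids, n_tcw), (other_ids, n_mutations - n_tcw)):
        flat, owner, contigs = gather(ids)
        if count > flat.size:
            raise ValueError("not enough eligible cytosine sites")
        chosen = rng.choice(flat.size, size=count, replace=False)
        for j in chosen:
            contig = contigs[int(owner[j])]
            pos0 = int(flat[j]) - 1
            plus = genome.sequence(contig)[pos0]
            ref, alt = ("C", "T") if plus == "C" else ("G", "A")
            variants.append(SomaticVariant(contig, pos0 + 1, ref, alt,
                                           variant_class=VariantClass.SBS,
                                           sample_id=sample_id))
    variants.sort(key=lambda v: (v.contig, v.position))
    return variants


def attach_read_support(
    variants: list[SomaticVariant],
    depth_mean: float = 60,
    vaf_mean: float = 0.35,
    contaminant_fraction: float = 0.0,
    seed: int = 0,
    ledger: TruthLedger | None = None,
    min_alt: int = 3,
    min_total: int = 10,
    min_vaf: float = 0.05,
) -> list[SomaticVariant]:
    """Give every variant (alt_reads, total_reads, vaf) in place.

    Clean variants draw depth from ``min_total + Poisson(depth_mean -
    min_total)`` (shifted so the mean equals ``depth_mean`` while always
    passing the depth filter) and alt reads from a Binomial clipped into
    the passing range.  A ``contaminant_fraction`` of variants is instead
    given support that violates at least one threshold — too few alt
    reads, too shallow a site, or a VAF at or below the cutoff — and
    recorded in the ledger so filter tests can demand exact recovery.
    """
    if depth_mean < 1:
        raise ValueError("depth_mean must be at least 1")
    if not 0 <= contaminant_fraction <= 1:
        raise ValueError("contaminant_fraction must lie in [0, 1]")
    if not 0 < vaf_mean <= 1:
        raise ValueError("vaf_mean must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(variants)
    n_bad = int(round(contaminant_fraction * n))
    bad = set(rng.choice(n, size=n_bad, replace=False)) if n_bad else set()
    flagged = []
    shift = max(0.0, depth_mean - min_total)
    for i, v in enumerate(variants):
        if i in bad:
            mode = rng.integers(3)
            if mode == 0:  # too few supporting reads
                total = min_total + int(rng.poisson(shift))
                alt = int(rng.integers(1, min_alt))
                total = max(total, int(np.ceil(alt / 0.5)))  # keep VAF comfortably high
            elif mode == 1:  # shallow site
                total = int(rng.integers(min_alt, min_total))
                alt = int(rng.integers(min_alt, total + 1))
            else:  # VAF at or below the cutoff (exercises strict inequality)
                total = int(20 * rng.integers(4, 8))
                alt = max(min_alt, int(np.floor(min_vaf * total)))
            flagged.append(v.key)
        else:
            total = min_total + int(rng.poisson(shift))
            alt = int(rng.binomial(total, vaf_mean))
            lo = max(min_alt, int(np.floor(min_vaf * total)) + 1)
            alt = min(max(alt, lo), total)
        v.alt_reads, v.total_reads = alt, total
        v.vaf = alt / total
    if ledger is not None:
        ledger.contaminated = flagged
        ledger.read_support_model = {
            "depth_mean": depth_mean, "vaf_mean": vaf_mean,
            "contaminant_fraction": contaminant_fraction,
        }
    return variants


# ---------------------------------------------------------------------------
# Indels
# ---------------------------------------------------------------------------

_INDEL_PLAN = {
    # category -> (kind, length); MH deletions get their own search rule
    "ins_1bp_TA": ("ins", 1), "ins_1bp_CG": ("ins", 1),
    "del_1bp_TA": ("del", 1), "del_1bp_CG": ("del", 1),
    "indel_2bp": ("ins", 2), "indel_3bp": ("ins", 3), "indel_4bp": ("ins", 4),
    "del_2bp_MH": ("del_mh", 2), "del_3bp_MH": ("del_mh", 3), "del_4bp_MH": ("del_mh", 4),
    "indel_5plus": ("del", 12),
}


def plant_indels(
    genome: SyntheticGenome,
    counts_by_category: dict[str, int],
    seed: int,
    occupied: dict[str, set[int]] | None = None,
    sample_id: str = "",
) -> tuple[list[SomaticVariant], TruthLedger]:
    """Plant left-aligned indels whose category is guaranteed by construction.

    Microhomology deletions are placed at genome positions whose deleted
    span naturally shares at least 2 identical leading bases with the
    sequence immediately 3' of the junction, so the classifier's condition
    holds exactly.  Plain 2-4 bp events are insertions (immune to
    accidental microhomology); 1 bp events delete/insert the stated base
    class.  All events avoid chrM, each other, and ``occupied`` positions.
    """
    unknown = set(counts_by_category) - set(_INDEL_PLAN)
    if unknown:
        raise ValueError(f"unknown indel categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    occupied = occupied if occupied is not None else {}
    ledger = TruthLedger(seed=seed)
    variants: list[SomaticVariant] = []

    def is_free(contig, start0, end0):
        used = occupied.setdefault(contig, set())
        return all(p not in used for p in range(start0, end0))

    def reserve(contig, start0, end0):
        occupied.setdefault(contig, set()).update(range(start0 - 1, end0 + 1))

    contigs = genome.nuclear_contigs
    for category in sorted(counts_by_category):
        count = counts_by_category[category]
        kind, length = _INDEL_PLAN[category]
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 200 * max(count, 1) + 2000:
                raise ValueError(
                    f"genome too small to place {count} {category} events"
                )
            contig = contigs[int(rng.integers(len(contigs)))]
            seq = genome.sequence(contig)
            L = len(seq)
            if kind == "ins":
                a = int(rng.integers(1, L - 2))  # 0-based anchor
                if category == "ins_1bp_TA":
                    ins = "T" if rng.integers(2) else "A"
                elif category == "ins_1bp_CG":
                    ins = "C" if rng.integers(2) else "G"
                else:
                    ins = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
                if seq[a] == ins[-1]:  # would left-shift; keep truth left-aligned
                    continue
                if not is_free(contig, a, a + 2):
                    continue
                ref, alt, pos = seq[a], seq[a] + ins, a + 1
                reserve(contig, a, a + 2)
            else:
                if category == "indel_5plus":
                    length = int(rng.integers(5, 31))
                p = int(rng.integers(1, L - length - 4))  # 0-based first deleted base
                deleted = seq[p:p + length]
                if category == "del_1bp_TA" and deleted not in "TA":
                    continue
                if category == "del_1bp_CG" and deleted not in "CG":
                    continue
                if seq[p - 1] == deleted[-1]:  # not left-aligned here
                    continue
                flank = seq[p + length:p + length + 2]
                has_mh = length >= 2 and deleted[:2] == flank
                if kind == "del_mh" and not has_mh:
                    continue
                if kind == "del" and length >= 2 and length <= 4 and has_mh:
                    continue
                if not is_free(contig, p - 1, p + length + 2):
                    continue
                ref, alt, pos = seq[p - 1:p + length], seq[p - 1], p
                reserve(contig, p - 1, p + length + 2)
            variants.append(SomaticVariant(contig, pos, ref, alt, sample_id=sample_id))
            ledger.planted_indels.append(PlantedIndel(contig, pos, ref, alt, category))
            placed += 1
    order = sorted(range(len(variants)), key=lambda i: (variants[i].contig, variants[i].position))
    variants = [variants[i] for i in order]
    ledger.planted_indels = [ledger.planted_indels[i] for i in order]
    return variants, ledger


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

def plant_structural_variants(
    genome: SyntheticGenome,
    counts_by_type: dict[str, int],
    seed: int,
    sample_id: str = "",
) -> tuple[list[SvRecord], int]:
    """Emit Manta-style SV records: symbolic DEL/DUP/INV plus BND mate pairs.

    Deletions span 600-5000 bp (always past the >500 bp counting
    threshold); translocations join two distinct nuclear contigs and are
    written as a properly mated breakend pair that the tally deduplicates
    to one event.  Returns the records and the number of planted events.
    """
    allowed = {"deletion_gt500", "duplication", "inversion", "translocation"}
    unknown = set(counts_by_type) - allowed
    if unknown:
        raise ValueError(f"unknown SV types: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    contigs = genome.nuclear_contigs
    records: list[SvRecord] = []
    n_events = 0
    serial = 0
    type_map = {"deletion_gt500": "DEL", "duplication": "DUP", "inversion": "INV"}
    for svtype in sorted(counts_by_type):
        for _ in range(counts_by_type[svtype]):
            serial += 1
            n_events += 1
            if svtype == "translocation":
                if len(contigs) < 2:
                    raise ValueError("translocations need at least two nuclear contigs")
                c1, c2 = rng.choice(len(contigs), size=2, replace=False)
                n1, n2 = contigs[int(c1)], contigs[int(c2)]
                p1 = int(rng.integers(100, genome.length(n1) - 100))
                p2 = int(rng.integers(100, genome.length(n2) - 100))
                b1 = genome.base_at(n1, p1)
                b2 = genome.base_at(n2, p2)
                id1, id2 = f"BND_{serial}_1", f"BND_{serial}_2"
                records.append(SvRecord(n1, p1, id1, b1, f"{b1}[{n2}:{p2}[",
                                        "BND", mate_id=id2, sample_id=sample_id))
                records.append(SvRecord(n2, p2, id2, b2, f"]{n1}:{p1}]{b2}",
                                        "BND", mate_id=id1, sample_id=sample_id))
            else:
                contig = contigs[int(rng.integers(len(contigs)))]
                span = int(rng.integers(600, min(5000, genome.length(contig) // 4)))
                pos = int(rng.integers(100, genome.length(contig) - span - 100))
                records.append(
                    SvRecord(contig, pos, f"SV_{serial}", genome.base_at(contig, pos),
                             f"<{type_map[svtype]}>", type_map[svtype],
                             end=pos + span, sample_id=sample_id)
                )
    return records, n_events


# ---------------------------------------------------------------------------
# Replication timing
# ---------------------------------------------------------------------------

@dataclass
class TimingTrack:
    """Fixed-width bins over nuclear contigs with timing values.

    ``quintiles`` is the generator's intended quintile (1 = earliest) per
    bin; the emitted value encodes it (value 5.0 for Q1 down to 1.0 for
    Q5, the early-is-high dialect) so rank partitioning recovers the
    intent exactly.
    """

    intervals: list[tuple[str, int, int, float]]  # contig, start0, end0, value
    quintiles: list[int]

    def __post_init__(self):
        self._by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per: dict[str, list[tuple[int, int, int]]] = {}
        for (contig, start, end, _), q in zip(self.intervals, self.quintiles):
            per.setdefault(contig, []).append((start, end, q))
        for contig, rows in per.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            qs = np.array([r[2] for r in rows])
            self._by_contig[contig] = (starts, ends, qs)

    def quintile_of(self, contig: str, positions0: np.ndarray) -> np.ndarray:
        """Quintile (1-5) per 0-based position; 0 when uncovered."""
        out = np.zeros(len(positions0), dtype=int)
        if contig not in self._by_contig:
            return out
        starts, ends, qs = self._by_contig[contig]
        i = np.searchsorted(starts, positions0, side="right") - 1
        valid = (i >= 0) & (positions0 < ends[np.clip(i, 0, None)])
        out[valid] = qs[i[valid]]
        return out

    def site_weights(self, contig: str, sites_1based: np.ndarray,
                     bias: dict[int, float]) -> np.ndarray:
        q = self.quintile_of(contig, np.asarray(sites_1based) - 1)
        lut = np.zeros(6)
        for k, v in bias.items():
            lut[int(k)] = v
        return lut[q]


def generate_timing_track(
    genome: SyntheticGenome,
    n_bins: int,
    bias: dict[int, float] | None = None,
    seed: int = 0,
) -> TimingTrack:
    """Tile nuclear contigs with ~``n_bins`` fixed-width bins and quintiles.

    Bin quintiles are a seeded random balanced assignment (each quintile
    holds an equal number of bins ± 1); the ``bias`` map (quintile ->
    relative mutation rate) is carried by the caller into
    :func:`plant_sbs_from_signatures`.  Trailing sequence shorter than one
    bin is left uncovered, mirroring real track gaps.
    """
    if n_bins < 5:
        raise ValueError("need at least 5 bins for quintiles")
    total = sum(genome.length(c) for c in genome.nuclear_contigs)
    width = total // n_bins
    if width < 1 or width > min(genome.length(c) for c in genome.nuclear_contigs):
        raise ValueError("bins wider than the smallest nuclear contig")
    bins: list[tuple[str, int, int]] = []
    for contig in genome.nuclear_contigs:
        L = genome.length(contig)
        for start in range(0, L - width + 1, width):
            bins.append((contig, start, start + width))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bins))
    quintiles = np.zeros(len(bins), dtype=int)
    for rank, b in enumerate(order):
        quintiles[b] = rank % 5 + 1
    intervals = [
        (contig, start, end, float(6 - q))
        for (contig, start, end), q in zip(bins, quintiles)
    ]
    return TimingTrack(intervals, [int(q) for q in quintiles])


# ---------------------------------------------------------------------------
# Writers (plain-text FASTA / VCF 4.2 / bedGraph)
# ---------------------------------------------------------------------------

def write_fasta(genome: SyntheticGenome, path, line_width: int = 70) -> None:
    """Write the genome as FASTA and build a .fai index beside it."""
    with open(path, "w") as fh:
        for name in genome.contig_names():
            fh.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(path), rebuild=True)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
"""


def write_vcf(variants: list[SomaticVariant], path, sample_id: str = "TUMOR",
              genome: SyntheticGenome | None = None) -> None:
    """Write somatic calls as a sorted VCF 4.2 with AD/DP/AF FORMAT fields."""
    lines = [_VCF_HEADER]
    if genome is not None:
        for name in genome.contig_names():
            lines.append(f"##contig=<ID={name},length={genome.length(name)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n")
    for v in sorted(variants, key=lambda x: (x.contig, x.position, x.alt_allele)):
        if v.alt_reads is not None and v.total_reads is not None:
            ref_reads = v.total_reads - v.alt_reads
            fmt = f"{ref_reads},{v.alt_reads}:{v.total_reads}:{v.vaf:.4f}"
        else:
            fmt = ".,.:.:."
        lines.append(
            f"{v.contig}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t"
            f"{v.filter_status}\t.\tAD:DP:AF\t{fmt}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)


_SV_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
"""


def write_sv_vcf(records: list[SvRecord], path,
                 genome: SyntheticGenome | None = None) -> None:
    lines = [_SV_HEADER]
    if genome is not None:
        for name in genome.contig_names():
            lines.append(f"##contig=<ID={name},length={genome.length(name)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for r in sorted(records, key=lambda x: (x.contig, x.position, x.record_id)):
        info = [f"SVTYPE={r.svtype}"] if r.svtype else []
        if r.end is not None:
            info.append(f"END={r.end}")
        if r.mate_id:
            info.append(f"MATEID={r.mate_id}")
        lines.append(
            f"{r.contig}\t{r.position}\t{r.record_id}\t{r.ref}\t{r.alt}\t.\tPASS\t"
            + (";".join(info) or ".") + "\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)


def write_bedgraph(track: TimingTrack, path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, value in track.intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{value:g}\n")


def simulate_catalog_matrix(
    signatures: SignatureSet,
    names: list[str],
    n_samples: int = 40,
    n_mutations: int = 10_000,
    alpha: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial 96 x S catalog matrix from a planted signature mixture.

    Per-sample exposures are Dirichlet(alpha) draws — the default
    concentration below 1 yields the sparse, one-process-dominated
    exposures real tumors show, which also anchors de novo factorization.
    Returns ``(catalog_matrix, true_exposures)`` with exposures S x K.
    """
    rng = np.random.default_rng(seed)
    W = np.column_stack([signatures.column(n) for n in names])
    exposures = rng.dirichlet([alpha] * len(names), size=n_samples)
    V = np.stack(
        [rng.multinomial(n_mutations, W @ e) for e in exposures], axis=1
    ).astype(float)
    return V, exposures


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Relative frequencies of small-indel categories in a simulated tumor,
#: shaped like the murine tumor landscape (single T/A events dominate).
DEFAULT_INDEL_MIX = {
    "del_1bp_TA": 0.30, "ins_1bp_TA": 0.20, "del_1bp_CG": 0.10, "ins_1bp_CG": 0.06,
    "indel_2bp": 0.08, "indel_3bp": 0.05, "indel_4bp": 0.04,
    "del_2bp_MH": 0.04, "del_3bp_MH": 0.03, "del_4bp_MH": 0.02, "indel_5plus": 0.08,
}
DEFAULT_SV_MIX = {"deletion_gt500": 0.4, "duplication": 0.2,
                  "inversion": 0.2, "translocation": 0.2}
#: Early-replication bias of APOBEC-driven tumors (quintile -> relative rate).
DEFAULT_EARLY_BIAS = {1: 2.0, 2: 1.4, 3: 1.0, 4: 0.8, 5: 0.6}
UNIFORM_BIAS = {q: 1.0 for q in range(1, 6)}


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    sbs_variants: list[SomaticVariant]
    indel_variants: list[SomaticVariant]
    sv_records: list[SvRecord]
    ledger: TruthLedger
    planted_enrichment: float


@dataclass
class CohortSimulation:
    genome: SyntheticGenome
    timing_track: TimingTrack
    samples: list[SimulatedSample]
    signatures: SignatureSet
    seed: int

    def sample(self, sample_id: str) -> SimulatedSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def _planted_enrichment(ledger: TruthLedger, idx: ContextSiteIndex,
                        genome: SyntheticGenome) -> float:
    """Truth enrichment score implied by the planted channels."""
    f = idx.tcw_fraction()
    informative = tcw = 0
    tcw_ctx = {_CONTEXT_ID[("T", "C", "A")], _CONTEXT_ID[("T", "C", "T")]}
    for p in ledger.planted_sbs:
        if p.contig == genome.mito_name:
            continue
        five, ref, alt, three = parse_channel(SBS96_CHANNELS[p.channel])
        if ref != "C" or alt == "A":
            continue
        informative += 1
        if CHANNEL_CONTEXT[p.channel] in tcw_ctx:
            tcw += 1
    if informative == 0:
        return float("nan")
    return (tcw / informative) / f


def simulate_cohort(
    n_tumors: int = 15,
    n_controls: int = 15,
    *,
    contig_lengths: tuple[int, ...] = (300_000, 200_000),
    gc_fraction: float = 0.42,
    n_sbs: int = 3000,
    tumor_weights: dict[str, float] | None = None,
    control_weights: dict[str, float] | None = None,
    indel_base: int = 40,
    indel_per_es: float = 25.0,
    sv_base: int = 4,
    sv_per_es: float = 6.0,
    timing_bins: int = 100,
    tumor_timing_bias: dict[int, float] | None = None,
    depth_mean: float = 60,
    vaf_mean: float = 0.35,
    contaminant_fraction: float = 0.0,
    signatures: SignatureSet | None = None,
    seed: int = 0,
) -> CohortSimulation:
    """The default synthetic cohort: SBS2-dominant tumors vs flat controls.

    Tumors plant an SBS2-heavy mixture with an early-replication bias and
    enrichment-coupled indel and SV loads (load = base + rate * (ES - 1));
    controls plant the flat aging background uniformly with baseline
    loads.  All per-sample randomness derives from ``seed``.
    """
    from .signatures import synthetic_reference_signatures

    signatures = signatures or synthetic_reference_signatures()
    tumor_weights = tumor_weights or {"SBS2": 0.6, "SBS5": 0.4}
    control_weights = control_weights or {"SBS5": 1.0}
    tumor_timing_bias = tumor_timing_bias or DEFAULT_EARLY_BIAS

    rng = np.random.default_rng(seed)
    genome = generate_genome(len(contig_lengths), list(contig_lengths),
                             gc_fraction, seed=int(rng.integers(2**31)))
    idx = ContextSiteIndex(genome)
    track = generate_timing_track(genome, timing_bins, seed=int(rng.integers(2**31)))

    samples: list[SimulatedSample] = []
    plan = [("tumor", i + 1) for i in range(n_tumors)] + \
           [("control", i + 1) for i in range(n_controls)]
    for group, number in plan:
        sid = f"{group}_{number:02d}"
        s_seed = int(rng.integers(2**31))
        sub = np.random.default_rng(s_seed)
        weights = tumor_weights if group == "tumor" else control_weights
        bias = tumor_timing_bias if group == "tumor" else UNIFORM_BIAS
        sbs, ledger = plant_sbs_from_signatures(
            genome, n_sbs, weights, signatures, seed=int(sub.integers(2**31)),
            timing_track=track, timing_bias=bias, site_index=idx, sample_id=sid,
        )
        es = _planted_enrichment(ledger, idx, genome)
        boost = max(0.0, es - 1.0)
        n_indels = indel_base + int(round(indel_per_es * boost))
        indel_counts: dict[str, int] = {}
        remaining = n_indels
        cats = sorted(DEFAULT_INDEL_MIX)
        for cat in cats[:-1]:
            c = int(round(DEFAULT_INDEL_MIX[cat] * n_indels))
            indel_counts[cat] = min(c, remaining)
            remaining -= indel_counts[cat]
        indel_counts[cats[-1]] = max(0, remaining)
        occupied = {v.contig: {v.position - 1} for v in sbs}
        for v in sbs:
            occupied.setdefault(v.contig, set()).add(v.position - 1)
        indels, indel_ledger = plant_indels(
            genome, indel_counts, seed=int(sub.integers(2**31)),
            occupied=occupied, sample_id=sid,
        )
        ledger.planted_indels = indel_ledger.planted_indels
        n_svs = sv_base + int(round(sv_per_es * boost))
        sv_counts: dict[str, int] = {}
        remaining = n_svs
        for svt in sorted(DEFAULT_SV_MIX)[:-1]:
            c = int(round(DEFAULT_SV_MIX[svt] * n_svs))
            sv_counts[svt] = min(c, remaining)
            remaining -= sv_counts[svt]
        sv_counts[sorted(DEFAULT_SV_MIX)[-1]] = max(0, remaining)
        if len(genome.nuclear_contigs) < 2:
            # translocations need two contigs; count them as inversions
            sv_counts["inversion"] = sv_counts.get("inversion", 0) + \
                sv_counts.pop("translocation", 0)
        svs, n_sv_events = plant_structural_variants(
            genome, sv_counts, seed=int(sub.integers(2**31)), sample_id=sid)
        ledger.planted_sv_count = n_sv_events
        attach_read_support(
            sbs + indels, depth_mean=depth_mean, vaf_mean=vaf_mean,
            contaminant_fraction=contaminant_fraction,
            seed=int(sub.integers(2**31)), ledger=ledger,
        )
        samples.append(SimulatedSample(sid, group, sbs, indels, svs, ledger, es))
    return CohortSimulation(genome, track, samples, signatures, seed)
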