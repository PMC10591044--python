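"""Mutation topography: replication-timing quintiles and clustered events.

Timing tracks (bedGraph-style intervals with a numeric value) are ranked
and split into five groups of equal assayed length; mutation density and
the TC>TT fraction are then compared across quintiles.  Clustered
mutations are called by inter-mutation distance: runs of at least 6
events within 1 kb of each other are kataegis, isolated runs of 2-5
events within 10 kb are omikli, and everything else is dispersed.  The
cluster thresholds follow the conventions of the kataegis/omikli
literature and are configurable — they are operating definitions, not
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .reference import Reference
from .variants import SomaticVariant, VariantClass

KATAEGIS_IMD = 1_000
KATAEGIS_MIN_MEMBERS = 6
OMIKLI_IMD = 10_000


@dataclass
class TimingQuintiles:
    """Non-overlapping intervals labeled with quintile 1 (earliest) to 5."""

    intervals: list[tuple[str, int, int, float, int]]  # contig, start0, end0, value, quintile

    def __post_init__(self):
        per: dict[str, list[tuple[int, int, int]]] = {}
        for contig, start, end, _, q in self.intervals:
            per.setdefault(contig, []).append((start, end, q))
        self._by_contig = {}
        for contig, rows in per.items():
            rows.sort()
            self._by_contig[contig] = (
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]),
            )

    def quintile_of(self, contig: str, position: int) -> int:
        """Quintile of a 1-based position, or 0 when off the track."""
        if contig not in self._by_contig:
            return 0
        starts, ends, qs = self._by_contig[contig]
        i = int(np.searchsorted(starts, position - 1, side="right")) - 1
        if i >= 0 and position - 1 < ends[i]:
            return int(qs[i])
        return 0

    def assayed_length(self, quintile: int) -> int:
        return sum(end - start for _, start, end, _, q in self.intervals if q == quintile)


def assign_timing_quintiles(
    track: list[tuple[str, int, int, float]], early_is_high: bool = True
) -> TimingQuintiles:
    """Rank bins by timing value and split into 5 equal-length groups.

    ``early_is_high`` states the track's dialect (whether a large value
    means early replication); ties break deterministically by genomic
    order.  Quintile 1 is earliest.
    """
    if not track:
        raise ValueError("empty timing track")
    contig_order = {}
    for contig, *_ in track:
        contig_order.setdefault(contig, len(contig_order))
    key = (lambda b: (-b[3], contig_order[b[0]], b[1])) if early_is_high else \
          (lambda b: (b[3], contig_order[b[0]], b[1]))
    ordered = sorted(track, key=key)
    total = sum(end - start for _, start, end, _ in ordered)
    labeled = []
    cum = 0
    for contig, start, end, value in ordered:
        q = min(4, cum * 5 // total) + 1
        labeled.append((contig, start, end, value, int(q)))
        cum += end - start
    return TimingQuintiles(labeled)


@dataclass
class QuintileCounts:
    counts: np.ndarray            # raw mutation count per quintile (index 0 = Q1)
    normalized: np.ndarray        # count / max(count)
    n_unassigned: int
    chi2_p: float | None = None
    chi2_statistic: float | None = None


def mutations_per_quintile(
    variants: list[SomaticVariant],
    quintiles: TimingQuintiles,
    comparison: "QuintileCounts | None" = None,
) -> QuintileCounts:
    """Raw and max-normalized mutation counts per replication-timing quintile.

    Variants off the assayed track are dropped and counted in
    ``n_unassigned``.  When a comparison group is given, a chi-square test
    of the 2x5 contingency table between the groups is attached.
    """
    counts = np.zeros(5, dtype=int)
    unassigned = 0
    for v in variants:
        q = quintiles.quintile_of(v.contig, v.position)
        if q == 0:
            unassigned += 1
        else:
            counts[q - 1] += 1
    if counts.sum() == 0:
        raise ValueError("no mutations fall on the assayed timing track")
    result = QuintileCounts(counts, counts / counts.max(), unassigned)
    if comparison is not None:
        stat, p, _, _ = stats.chi2_contingency(np.vstack([counts, comparison.counts]))
        result.chi2_statistic, result.chi2_p = float(stat), float(p)
    return result


def tcw_to_t_fraction_per_quintile(
    variants: list[SomaticVariant],
    quintiles: TimingQuintiles,
    reference: Reference,
) -> np.ndarray:
    """Percentage of TC>TT mutations among all mutations, per quintile.

    The numerator is pyrimidine-normalized C>T with a 5' T (TC>TT on
    either strand).  Quintiles holding no mutations at all yield NaN —
    an undefined share, deliberately distinct from 0%.
    """
    from .spectrum import trinucleotide_context, parse_channel, SBS96_CHANNELS, ContextError

    all_counts = np.zeros(5)
    tct_counts = np.zeros(5)
    for v in variants:
        q = quintiles.quintile_of(v.contig, v.position)
        if q == 0:
            continue
        all_counts[q - 1] += 1
        if v.variant_class is not VariantClass.SBS:
            continue
        try:
            channel = trinucleotide_context(v, reference)
        except ContextError:
            continue
        five, ref, alt, _ = parse_channel(SBS96_CHANNELS[channel])
        if ref == "C" and alt == "T" and five == "T":
            tct_counts[q - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(all_counts > 0, 100.0 * tct_counts / all_counts, np.nan)


@dataclass
class ClusterCall:
    contig: str
    members: list[int] = field(default_factory=list)  # sorted 1-based positions
    cluster_class: str = "dispersed"

    @property
    def span(self) -> int:
        return self.members[-1] - self.members[0] if len(self.members) > 1 else 0

    @property
    def n_members(self) -> int:
        return len(self.members)


def _runs(positions: np.ndarray, imd: int) -> list[np.ndarray]:
    """Maximal runs of consecutive positions with gaps <= imd."""
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > imd)
    return np.split(positions, breaks + 1)


def detect_clusters(
    variants: list[SomaticVariant],
    kataegis_imd: int = KATAEGIS_IMD,
    kataegis_min: int = KATAEGIS_MIN_MEMBERS,
    omikli_imd: int = OMIKLI_IMD,
) -> list[ClusterCall]:
    """Partition mutations into kataegis, omikli, and dispersed calls.

    Kataegis: maximal runs of >= ``kataegis_min`` mutations with
    inter-mutation distance <= ``kataegis_imd``.  Among the remaining
    mutations, runs of 2-5 with IMD <= ``omikli_imd`` are omikli; all
    else is dispersed.  Every variant lands in exactly one call.
    """
    calls: list[ClusterCall] = []
    per_contig: dict[str, list[int]] = {}
    for v in variants:
        per_contig.setdefault(v.contig, []).append(v.position)
    for contig in sorted(per_contig):
        positions = np.sort(np.array(per_contig[contig]))
        leftovers = []
        for run in _runs(positions, kataegis_imd):
            if run.size >= kataegis_min:
                calls.append(ClusterCall(contig, [int(p) for p in run], "kataegis"))
            else:
                leftovers.extend(int(p) for p in run)
        for run in _runs(np.array(sorted(leftovers)), omikli_imd):
            if 2 <= run.size <= 5:
                calls.append(ClusterCall(contig, [int(p) for p in run], "omikli"))
            else:
                for p in run:
                    calls.append(ClusterCall(contig, [int(p)], "dispersed"))
    return calls


def cluster_class_counts(calls: list[ClusterCall]) -> dict[str, int]:
    """Number of *variants* (not calls) per cluster class."""
    counts = {"dispersed": 0, "omikli": 0, "kataegis": 0}
    for c in calls:
        counts[c.cluster_class] += c.n_members
    return counts
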