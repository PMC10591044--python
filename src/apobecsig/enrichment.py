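"""APOBEC TCW enrichment score, exact-test significance, and stratification.

The enrichment score compares the fraction of mutated cytosines that sit in
the APOBEC-preferred 5'-TCW-3' motif (W = A or T, pyrimidine strand) with
the fraction of background cytosines in TCW across 41-base windows (20
bases either side) around each mutation:

    ES = (Mut_TCW / Con_TCW) / (Mut_C / Con_C)

Counting conventions (see docs/methods.md for rationale):

* Mutations are pyrimidine-normalized; background cytosines are counted on
  both strands (C positions, plus G positions read as reverse-strand C).
* The trinucleotide context of a background position is read from the
  reference, so motifs at window edges use flanks just outside the window.
* The mutated position and its two immediate neighbors are excluded from
  their own window's Con tallies.  Those are exactly the positions whose
  trinucleotide context overlaps the mutated base: the center is a mutated
  cytosine by construction and its neighbors can never form an independent
  TCW, so counting them as background couples the two ratios and biases
  the score (~5% upward under the null).  With them excluded the score is
  an unbiased estimator of fold-enrichment under uniform placement.
* Overlapping windows double-count background, matching per-substitution
  aggregation.

Significance is a one-sided Fisher exact test on
[Mut_TCW, Mut_C - Mut_TCW; Con_TCW, Con_C - Con_TCW] (alternative: the
mutated TCW fraction is greater), Benjamini-Hochberg adjusted across the
cohort; samples with q < 0.1 and score > 1 are ES-high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .reference import Reference
from .variants import SomaticVariant, VariantClass

DEFAULT_FLANK = 20
DEFAULT_Q_THRESHOLD = 0.1
LOW_BURDEN_WARNING = 50


@dataclass
class EnrichmentCounts:
    """Aggregated numerator/denominator tallies for one sample."""

    mut_tcw: int
    mut_c: int
    con_tcw: int
    con_c: int
    n_windows: int = 0
    mut_tca: int = 0
    con_tca: int = 0

    def __post_init__(self):
        if min(self.mut_tcw, self.mut_c, self.con_tcw, self.con_c) < 0:
            raise ValueError("enrichment counts must be nonnegative")
        if self.mut_tcw > self.mut_c:
            raise ValueError("mut_tcw cannot exceed mut_c")
        if self.con_tcw > self.con_c:
            raise ValueError("con_tcw cannot exceed con_c")


@dataclass
class EnrichmentResult:
    sample_id: str
    score: float
    p_value: float
    q_value: float | None = None
    stratum: str | None = None
    counts: EnrichmentCounts | None = None
    warnings: list[str] = field(default_factory=list)


class _ContextMasks:
    """Per-contig boolean masks and prefix sums for O(1) window tallies.

    ``cg[i]`` marks a cytosine on either strand at position i;
    ``tcw[i]`` marks positions whose pyrimidine-strand trinucleotide is
    TCA or TCT; ``tca[i]`` is the TCA-only subset.
    """

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        self.cg = is_c | is_g
        n = len(arr)
        prev = np.empty(n, dtype=np.uint8)
        nxt = np.empty(n, dtype=np.uint8)
        prev[1:], prev[0] = arr[:-1], 0
        nxt[:-1], nxt[-1] = arr[1:], 0
        A, T = ord("A"), ord("T")
        # plus-strand C in TCW: T C (A|T); minus-strand C (a G) in TCW on -:
        # plus strand reads (A|T)' G A' i.e. prev in {A,T}, next == A
        plus_w = is_c & (prev == T) & ((nxt == A) | (nxt == T))
        minus_w = is_g & (nxt == A) & ((prev == A) | (prev == T))
        self.tcw = plus_w | minus_w
        self.tca = (is_c & (prev == T) & (nxt == A)) | (is_g & (nxt == A) & (prev == T))
        self.cum_cg = np.concatenate(([0], np.cumsum(self.cg)))
        self.cum_tcw = np.concatenate(([0], np.cumsum(self.tcw)))
        self.cum_tca = np.concatenate(([0], np.cumsum(self.tca)))
        self.n = n


class EnrichmentContextIndex:
    """Lazy cache of :class:`_ContextMasks` per contig of a reference."""

    def __init__(self, reference: Reference):
        self.reference = reference
        self._masks: dict[str, _ContextMasks] = {}

    def masks(self, contig: str) -> _ContextMasks:
        if contig not in self._masks:
            if hasattr(self.reference, "sequence"):
                seq = self.reference.sequence(contig)
            else:
                seq = self.reference.fetch(contig, 0, self.reference.length(contig))
            self._masks[contig] = _ContextMasks(seq)
        return self._masks[contig]


def collect_enrichment_counts(
    variants: list[SomaticVariant],
    reference: Reference,
    flank: int = DEFAULT_FLANK,
    index: EnrichmentContextIndex | None = None,
) -> EnrichmentCounts:
    """Aggregate Mut/Con tallies over the windows of all informative variants.

    ``variants`` must already have passed the enrichment exclusions (SBS at
    C:G reference pairs, non-mitochondrial, not C->A).  Positions with N in
    their context never satisfy the motif masks and C/G counting skips
    non-ACGT characters, so ambiguous positions drop out of the Con tallies.
    """
    if not variants:
        raise ValueError("no_informative_mutations")
    idx = index or EnrichmentContextIndex(reference)
    mut_tcw = mut_c = con_tcw = con_c = mut_tca = con_tca = 0
    for v in variants:
        if v.variant_class is not VariantClass.SBS:
            raise ValueError(f"non-SBS variant {v.key} in enrichment input")
        masks = idx.masks(v.contig)
        p0 = v.position - 1
        if not masks.cg[p0]:
            raise ValueError(f"variant {v.key} is not at a C:G reference pair")
        mut_c += 1
        mut_tcw += int(masks.tcw[p0])
        mut_tca += int(masks.tca[p0])
        lo = max(0, p0 - flank)
        hi = min(masks.n, p0 + flank + 1)
        # exclude the mutated base and its two neighbors (context-coupled)
        ex_lo, ex_hi = max(lo, p0 - 1), min(hi, p0 + 2)
        con_c += int((masks.cum_cg[hi] - masks.cum_cg[lo])
                     - (masks.cum_cg[ex_hi] - masks.cum_cg[ex_lo]))
        con_tcw += int((masks.cum_tcw[hi] - masks.cum_tcw[lo])
                       - (masks.cum_tcw[ex_hi] - masks.cum_tcw[ex_lo]))
        con_tca += int((masks.cum_tca[hi] - masks.cum_tca[lo])
                       - (masks.cum_tca[ex_hi] - masks.cum_tca[ex_lo]))
    return EnrichmentCounts(
        mut_tcw=mut_tcw, mut_c=mut_c, con_tcw=con_tcw, con_c=con_c,
        n_windows=len(variants), mut_tca=mut_tca, con_tca=con_tca,
    )


def apobec_enrichment_score(counts: EnrichmentCounts) -> float:
    """The double ratio (Mut_TCW/Con_TCW)/(Mut_C/Con_C)."""
    if counts.mut_c == 0 or counts.con_tcw == 0 or counts.con_c == 0:
        raise ZeroDivisionError(
            "enrichment score undefined: mut_c, con_tcw and con_c must be positive"
        )
    return (counts.mut_tcw / counts.con_tcw) / (counts.mut_c / counts.con_c)


def enrichment_significance(
    counts: EnrichmentCounts, motif: str = "tcw"
) -> tuple[float, str]:
    """One-sided Fisher exact p for TCW enrichment.

    ``motif="tcw"`` (default) uses TCW in both margins; ``motif="tca_literal"``
    uses Mut_TCA against Con_TCW, reproducing the Methods wording verbatim.
    Returns ``(p_value, direction)`` with direction "enrichment".
    """
    if motif == "tcw":
        mut_m = counts.mut_tcw
    elif motif == "tca_literal":
        mut_m = counts.mut_tca
    else:
        raise ValueError(f"unknown motif mode {motif!r}")
    table = [
        [mut_m, counts.mut_c - mut_m],
        [counts.con_tcw, counts.con_c - counts.con_tcw],
    ]
    if min(min(row) for row in table) < 0:
        raise ValueError("negative cell in enrichment contingency table")
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p), "enrichment"


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, ties preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def stratify_samples(
    results: list[EnrichmentResult], q_threshold: float = DEFAULT_Q_THRESHOLD
) -> list[EnrichmentResult]:
    """Label ES_high (q below threshold AND score above 1) vs ES_low, in place.

    The score > 1 guard keeps significantly *depleted* samples out of the
    high stratum; the one-sided alternative is enrichment.
    """
    for r in results:
        if r.q_value is None:
            raise ValueError(f"sample {r.sample_id} has no q-value; run adjust_bh first")
        r.stratum = "ES_high" if (r.q_value < q_threshold and r.score > 1) else "ES_low"
    return results


def evaluate_cohort(
    variants_by_sample: dict[str, list[SomaticVariant]],
    reference: Reference,
    flank: int = DEFAULT_FLANK,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    motif: str = "tcw",
    index: EnrichmentContextIndex | None = None,
) -> list[EnrichmentResult]:
    """Score every sample, BH-adjust across the cohort, and stratify."""
    idx = index or EnrichmentContextIndex(reference)
    results = []
    for sample_id, variants in variants_by_sample.items():
        counts = collect_enrichment_counts(variants, reference, flank=flank, index=idx)
        p, _ = enrichment_significance(counts, motif=motif)
        res = EnrichmentResult(sample_id, apobec_enrichment_score(counts), p, counts=counts)
        if counts.mut_c < LOW_BURDEN_WARNING:
            res.warnings.append(f"only {counts.mut_c} informative mutations")
        results.append(res)
    qs = adjust_bh([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return stratify_samples(results, q_threshold)
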