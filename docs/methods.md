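# Methods

This note documents the models and procedures the package implements,
the conventions it adopts where the field's practice is ambiguous, the
defaults and why they were chosen, and what the synthetic-data tests do
and do not establish about real data.

## Variant input and quality filtering

Somatic calls are consumed as tumor/normal VCF 4.x (Mutect2-style for
substitutions and small indels, Manta-style for structural variants).
Multi-allelic records are split per ALT allele, with per-allele depths
from the tumor sample's AD field and totals from DP (or the AD sum).
Internal coordinates stay 1-based per the VCF convention; conversion to
0-based half-open happens only inside reference-window extraction.

A call survives quality filtering iff

- alt-supporting reads ≥ 3,
- total reads at the site ≥ 10,
- variant allele fraction strictly > 0.05,
- caller FILTER is PASS (when required, the default), and
- the contig is not excluded.

"Minimum" thresholds are inclusive and the VAF cutoff exclusive — a VAF
of exactly 0.05 is removed. Every removed variant carries machine-
readable reason codes, and the kept/removed lists always partition the
input. Mitochondrial exclusion keys on a configurable name set
({chrM, MT, chrMT, M}) and is applied by default only where the
enrichment score requires it, not globally.

## SBS-96 catalogs

Substitutions are reported on the pyrimidine strand: purine-reference
calls are reverse-complemented so the mutated base is C or T. Channels
follow the canonical COSMIC ordering (substitution major C>A…T>G, then
5' base, then 3' base, alphabetical). Calls at contig ends or with N in
the trinucleotide flank are excluded with reasons rather than guessed.
The catalog channel sum always equals the number of classifiable SBS,
and a genome-wide reverse complement leaves catalogs invariant (a
property test enforces both).

## The TCW enrichment score

For each informative substitution — an SBS at a C:G reference pair, off
the mitochondrial contig, and not C→A (nor its reverse-strand
equivalent G→T; C→A is confounded by oxidative processes) — the score
accumulates four tallies over a 41-base window (20 bases each side,
clipped at contig ends):

- `Mut_C` += 1; `Mut_TCW` += 1 iff the mutated cytosine's
  pyrimidine-strand context is TCA or TCT (W = A/T);
- `Con_C` += the number of window positions carrying a cytosine on
  either strand (C, or G read as reverse-strand C);
- `Con_TCW` += the number of those positions whose pyrimidine-strand
  trinucleotide is TCW.

and `ES = (Mut_TCW/Con_TCW)/(Mut_C/Con_C)`. Three counting conventions
matter and are fixed as follows:

1. **Background is double-stranded.** Mutations are pyrimidine-
   normalized, so the background must be too: G positions count as
   reverse-strand cytosines and WGA motifs as reverse-strand TCW.
2. **Contexts, not substrings.** A background position's motif status is
   decided by its trinucleotide context read from the reference, so
   positions near a window edge use flanking bases just outside the
   window. Counting only motifs wholly inside the window would
   undercount `Con_TCW` by the ratio 39/41 and bias every score upward.
3. **The mutated site and its two neighbors are not background.** The
   three positions whose trinucleotide context overlaps the mutated base
   are mechanically coupled to the mutation: the center is a mutated
   cytosine by construction, and its immediate neighbors can never form
   an independent TCW. Counting them inflates `Con_TCW`/`Con_C` in
   enriched samples and deflates both in depleted ones; measured on
   i.i.d. genomes, full-window counting biases the null score to
   ~1.04–1.05 and drags k-fold planted enrichment toward ~0.95·k.
   With the three positions excluded the score is an unbiased
   fold-enrichment estimator: across 1,000 simulated null samples the
   mean score is 1.00 ± 0.01 and planted 3-fold enrichment is recovered
   within a few percent.

Overlapping windows double-count background deliberately — tallies are
made per substitution and aggregated. Empty input is an explicit error
(`no_informative_mutations`), as is any zero denominator; scores are
never silently 0 or infinite. A warning is attached below 50
informative mutations, but no hard burden threshold is imposed.

Significance is a one-sided Fisher exact test (alternative: the mutated
TCW fraction exceeds the background fraction) on
`[Mut_TCW, Mut_C − Mut_TCW; Con_TCW, Con_C − Con_TCW]`, with
Benjamini–Hochberg adjustment across the cohort. A `tca_literal` mode
tests Mut_TCA against Con_TCW instead, for comparability with analyses
that wrote the table that way; TCW-in-both-margins is the default
because the two margins should measure the same motif. Samples with
q < 0.1 **and** score > 1 are ES-high; the score guard keeps significant
*depletion* out of the high stratum, since the alternative tested is
enrichment.

## Signature refitting

Per-sample exposures are obtained by iterative non-negative fitting of
the frequency-normalized catalog against a reference signature matrix
(96 × K, column-stochastic): starting from zero weights, each sweep
evaluates a golden-section line search on [0, 1] for every signature
and applies the single best error-reducing move, until no move reduces
the squared reconstruction error (the scheme popularized by per-sample
refitting tools, rather than a closed-form NNLS, so that the pruning
loop below behaves identically). Signatures holding under 6% of the
fitted mass (`prune_threshold`, configurable) are zeroed and the fit
repeated until stable. Reported weights are fractions of explained
mass; the residual fraction is reported as `unexplained`. Refitting the
reconstruction of a fit returns the same exposures to 1e-6
(idempotence, enforced by test). No trinucleotide-abundance
renormalization is applied between genome and exome — inputs are
assumed whole-genome.

### Reference signatures

The packaged reference set (`synthetic_reference_signatures()`) is a
**synthetic** stand-in shaped like an SBS1–SBS30 matrix: SBS2
concentrates C>T mass in TCN contexts (TCA and TCT dominant), SBS1
concentrates C>T at NCG (methyl-C deamination), SBS13 carries C>G at
TCN, SBS5 — the flat "aging" background used throughout the synthetic
cohorts — is exactly the uniform 96-vector, and the remaining columns
are seeded sparse random spectra that keep refitting honest. It is not
a reproduction of any published matrix; `read_signature_tsv` /
`write_signature_tsv` load and save 96-row COSMIC-layout TSVs so a real
reference matrix can be swapped in without code changes.

## De novo extraction

De novo signatures are extracted by NMF minimizing the generalized
Kullback–Leibler divergence with multiplicative updates (the objective
is non-increasing per update, a property test checks it on random
matrices). Extraction runs `n_restarts` (default 10; 20 in the
acceptance runs) random initializations derived from one seed and keeps
the lowest final divergence; signature columns are normalized to sum 1
with exposures rescaled compensatingly, so results are deterministic
given (data, rank, restarts, seed). The factorization rank is a user
parameter — no automatic rank selection is attempted. Matching to a
reference set is argmax cosine similarity and never fails; a poor match
is reported with its low similarity. Note the caveat inherent to NMF:
a signature lying inside the cone of the others (the flat background is
the extreme case) is identifiable only when some samples are strongly
dominated by it, which is why the recovery benchmarks draw exposures
from a sparse Dirichlet (α = 0.6).

## Indel and SV landscapes

Small indels (net length ≤ 200 bp) are classified, after left-aligning
the VCF representation, into: 1 bp insertions/deletions split by base
class (T/A vs C/G), plain 2/3/4 bp indels, 2/3/4 bp deletions with
microhomology, and a 5+ category (5–200 bp). Microhomology means the
deleted span shares an identical prefix of ≥ 2 bases with the sequence
immediately 3' of the junction, checked on the left-aligned form; the
MH category takes precedence over the plain size bins, and the ≥2 bp
threshold is configurable. This is a stated convention of this package
— coarser than the 83-channel COSMIC ID scheme, matching analyses that
report these nine-ish categories directly.

Structural variants are tallied from Manta-style records into
deletions > 500 bp (strict; deletions of 201–500 bp fall in neither the
indel nor the SV table and are counted separately), duplications,
inversions, translocations, and complex events. Breakend pairs are
deduplicated via MATEID and count once: inter-contig pairs are
translocations; intra-contig pairs classify by bracket orientation
(`t[p[` deletion-like, `]p]t` duplication-like, same-direction brackets
inversions); dangling mates count once with a warning.

## Topography

A replication-timing track (bedGraph intervals) is ranked by value and
split into five groups of equal assayed length (± one bin); ties break
by genomic order. Whether a high value means early replication is a
reference-dialect choice exposed as `early_is_high` (default True).
Mutations off the assayed track are dropped and counted, never imputed.
Per-quintile outputs are raw counts, counts normalized to the largest
quintile, the chi-square p for a 2×5 group contingency, and the TC→TT
share (pyrimidine-normalized C→T with 5' T) as a percentage of all
mutations in the quintile — an empty quintile reports NaN, not 0%.

Clustered mutagenesis is called from inter-mutation distance: maximal
runs of ≥ 6 events with consecutive spacing ≤ 1 kb are kataegis;
among the remaining mutations, runs of 2–5 within 10 kb are omikli;
everything else is dispersed, and every variant lands in exactly one
class. These thresholds follow the conventions of the clustered-
mutagenesis literature and are configurable — they are operating
definitions, not measurements. Under a uniform Poisson process at
density λ per bp, the expected clustered fraction is ≈ 2(1 − e^(−λ·d))
for omikli spacing d; at 1 mutation/Mb and d = 10 kb that is ~2%, and
the tests assert agreement with this expectation.

## Cohort statistics

Correlations are Pearson (with fitted line) or Spearman, two-sided,
pairwise-complete, requiring ≥ 3 pairs; constant vectors are errors,
not NaNs. Two-group comparisons default to two-sided. Mann–Whitney
uses an exact tie-free enumeration (the classic U-distribution
recurrence; two-sided p doubles the smaller tail) when the combined
sample is ≤ 20 without ties, and the tie-corrected normal approximation
otherwise; the exact path is verified against full enumeration and an
independent library implementation. Fisher 2×2 and chi-square use
standard exact/asymptotic machinery. The ES-stratified SV comparison
reports per-stratum medians and all pairwise Mann–Whitney p values,
skipping strata with fewer than two samples with a notice. The IHC
H-score is the exact weighted sum 1·(%weak) + 2·(%moderate) +
3·(%strong), bounded in [0, 300].

## The synthetic-data generator

The generator emulates the statistical structure of APOBEC3B-driven
murine tumors so that every downstream stage can be tested against
exact truth:

- **Genomes** are i.i.d. base draws at a requested GC fraction
  (default 0.42, mammalian-like), with no N bases — ambiguity handling
  is exercised via hand-written fixtures so planted truth stays exact.
  A mitochondrial contig (chrM, default 16 kb; smaller in tests) is
  always present.
- **Substitutions** draw a 96-channel from a signature mixture, then a
  uniform (or timing-biased) position among genome sites matching the
  channel's pyrimidine context, without replacement — one event per
  site, so ledger positions are unique. A few extra events (default 3)
  always land on chrM so the mitochondrial-exclusion rule is exercised
  on every run.
- **Enrichment planting** (`plant_enriched_cytosine_mutations`) places
  C:G mutations with P(TCW site) = k·f, where f is the genome's
  TCW-per-cytosine fraction, so the enrichment score converges to k;
  k = 1 is the uniform null.
- **Read support**: clean variants draw depth from
  `min_total + Poisson(depth_mean − min_total)` — the floor guarantees
  the generator contract that uncontaminated variants always pass the
  filters, while keeping the mean equal to `depth_mean` — and alt reads
  from a Binomial clipped into the passing range. A requested fraction
  of contaminants instead violates one threshold (too few alt reads, a
  shallow site, or VAF exactly at/below the cutoff — deliberately
  exercising the strict inequality) and is flagged in the ledger, so
  filter tests can demand exact set recovery.
- **Indels** are planted at searched sites whose local sequence
  guarantees the intended category: microhomology deletions at
  positions where the deleted span naturally repeats ≥ 2 bases into the
  3' flank, plain 2–4 bp events as insertions (immune to accidental
  microhomology), everything pre-left-aligned.
- **Timing tracks** tile nuclear contigs with fixed-width bins whose
  values encode a balanced random quintile assignment (value 5 = Q1,
  early-is-high), so rank partitioning recovers the intent exactly;
  planting then weights eligible sites by the per-quintile bias map.
- **The default cohort** is 15 "tumors" (60/40 SBS2/flat mixture,
  2-fold early-replication bias) vs 15 "controls" (flat only,
  uniform), 3,000 SBS each on a 500 kb genome, with indel and SV loads
  coupled to the planted enrichment (load = base + rate·(ES − 1):
  indels 40 + 25·ΔES, SVs 4 + 6·ΔES). These sizes keep the full suite
  and the acceptance script within minutes on one CPU while leaving all
  recovery margins wide.

Everything is driven by explicit integer seeds through numpy
Generators; identical seeds produce byte-identical FASTA/VCF/bedGraph/
JSON outputs (tested).

### What the generator does not emulate

Real tumor data differ in ways the synthetic tests deliberately ignore:
genome composition is not i.i.d. (CpG depletion, isochores, repeats),
callers produce artifact modes richer than the three planted
contamination types, signature exposures drift clonally within a tumor,
indels are caller-representation-messy beyond simple left-alignment,
and real replication timing is continuous and correlated, not balanced
random bins. Passing the recovery tests therefore demonstrates the
*correctness of the computations* — counting, normalization, exact
tests, optimizers — not robustness to caller artifacts or reference
quirks. The filter/exclusion semantics are where such robustness would
live, and they are exercised on explicit fixtures instead.

## Numerical choices

- Golden-section line searches run to an interval of 1e-12; coordinate
  sweeps stop below an error gain of 1e-15 (tight enough for the 1e-6
  idempotence guarantee).
- NMF multiplicative updates run to a relative divergence improvement
  of 1e-8 (max 2000 iterations), with machine-epsilon guards against
  division by zero; divergence is tracked every 10 iterations.
- BH adjustment delegates to the standard step-up implementation;
  exact ties in p-values receive equal q-values.
- Cosine similarity raises on zero vectors rather than returning 0.
- Reported q-values always satisfy q ≥ p; stratification refuses to run
  before adjustment.

## Limitations

- The packaged signature set is synthetic; quantitative exposure values
  on real data require a published reference matrix (drop-in TSV).
- The enrichment score is genome-wide per sample; no regional or
  per-chromosome enrichment maps.
- No YTCA/RTCA discrimination between APOBEC3A- and APOBEC3B-like
  contexts.
- Kataegis/omikli calls use fixed IMD definitions, not a background-
  density model; at very high mutation density (simulated catalogs
  above ~1/10 kb) nearly everything is, correctly but unhelpfully,
  clustered.
- The pipeline consumes caller output; it performs no alignment,
  calling, realignment, or subclonal deconvolution.
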