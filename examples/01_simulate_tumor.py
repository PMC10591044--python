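"""Simulate one APOBEC3B-driven tumor genome with known truth.

Builds a small reference, plants 2,000 substitutions from a 60/40
SBS2/flat mixture plus read support, and writes FASTA/VCF/bedGraph and
the JSON truth ledger that downstream recovery tests rely on.
"""

from pathlib import Path

import apobecsig as a
from apobecsig import synthetic_data as syn

outdir = Path("scratch/example_tumor")
outdir.mkdir(parents=True, exist_ok=True)

genome = a.generate_genome(n_contigs=2, lengths=[200_000, 100_000],
                           gc_fraction=0.42, seed=1)
refs = a.synthetic_reference_signatures()
track = syn.generate_timing_track(genome, n_bins=60, seed=1)

variants, ledger = a.plant_sbs_from_signatures(
    genome, 2000, {"SBS2": 0.6, "SBS5": 0.4}, refs, seed=1,
    timing_track=track, timing_bias={1: 2.0, 2: 1.4, 3: 1.0, 4: 0.8, 5: 0.6})
a.attach_read_support(variants, depth_mean=60, vaf_mean=0.35, seed=2,
                      ledger=ledger)

syn.write_fasta(genome, outdir / "genome.fa")
syn.write_vcf(variants, outdir / "tumor.vcf", sample_id="tumor01", genome=genome)
syn.write_bedgraph(track, outdir / "timing.bedgraph")
ledger.to_json(outdir / "truth.json")

n_mito = sum(1 for p in ledger.planted_sbs if p.contig == "chrM")
print(f"planted {len(ledger.planted_sbs)} SBS ({n_mito} on chrM)")
print(f"mixture truth: {ledger.signature_weights}")
print(f"outputs in {outdir}/ (FASTA + .fai, VCF with AD/DP/AF, bedGraph, truth JSON)")
# The ledger records every planted channel and position, so any
# downstream statistic can be checked against exact truth.
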