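"""Plant and classify the small-indel and structural-variant landscape.

Plants a known spectrum of indels (including microhomology deletions,
which are placed at sites whose deleted span naturally repeats in the 3'
flank) plus a handful of SVs, then recovers both catalogs exactly.
"""

import apobecsig as a
from apobecsig.spectrum import build_indel_catalog, tally_structural_variants

genome = a.generate_genome(2, [200_000, 100_000], gc_fraction=0.42, seed=9)

planted_indels = {
    "del_1bp_TA": 40, "ins_1bp_TA": 20, "del_1bp_CG": 12, "ins_1bp_CG": 8,
    "indel_2bp": 10, "indel_3bp": 6, "indel_4bp": 5,
    "del_2bp_MH": 6, "del_3bp_MH": 4, "del_4bp_MH": 3, "indel_5plus": 10,
}
indels, ledger = a.plant_indels(genome, planted_indels, seed=10)
catalog = build_indel_catalog(indels, genome, "tumor01")

print("indel category      planted  classified")
for cat in catalog.counts:
    print(f"  {cat:17s} {planted_indels.get(cat, 0):7d} {catalog.counts[cat]:10d}")
print(f"  total <200 bp     {sum(planted_indels.values()):7d} {catalog.total:10d}")

svs, n = a.plant_structural_variants(
    genome, {"deletion_gt500": 3, "duplication": 2, "inversion": 2,
             "translocation": 2}, seed=11)
tally = tally_structural_variants(svs, "tumor01")
print(f"\nplanted {n} SVs; tallied: {tally.counts} (total {tally.total})")
# Breakend mate pairs collapse to single translocation events; deletions
# count only above the 500 bp structural threshold.
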