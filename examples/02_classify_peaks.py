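"""Classify ChIP-seq peaks across three species by >=1 bp overlap.

Conserved peaks are present in focal, sister, and outgroup; gains exist only
in the focal species; losses are sister peaks shared with the outgroup but
absent from the focal species.
"""

from bindsel import Peak, PeakSet, classify_peaks, count_active_tissues, merge_peaks

focal = PeakSet("focal", [
    Peak("chr1", 100, 300, "f1"),   # shared with both -> conserved
    Peak("chr1", 1000, 1200, "f2"),  # focal only -> gain
    Peak("chr1", 2000, 2150, "f3"),  # shared with sister only -> unclassified
])
sister = PeakSet("sister", [
    Peak("chr1", 250, 400, "s1"),
    Peak("chr1", 2100, 2300, "s2"),
    Peak("chr1", 5000, 5200, "s3"),  # shared with outgroup, no focal -> loss
])
outgroup = PeakSet("outgroup", [
    Peak("chr1", 120, 260, "o1"),
    Peak("chr1", 5100, 5300, "o2"),
])

for peak_id, category in sorted(classify_peaks(focal, sister, outgroup).items()):
    print(f"{peak_id}: {category}")

# multi-tissue activity: merged sites vs per-tissue peak sets
tissues = [
    PeakSet("liver", [Peak("chr1", 100, 300, "L1")]),
    PeakSet("brain", [Peak("chr1", 150, 350, "B1"), Peak("chr1", 1000, 1100, "B2")]),
]
merged = merge_peaks([focal])
counts = count_active_tissues(merged, tissues)
for site, n in sorted(counts.items()):
    print(f"{site}: active in {n} of {len(tissues)} tissues")
# each merged site reports in how many tissues an overlapping peak exists.
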