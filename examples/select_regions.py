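"""Select 3' invariant regions from a toy annotation and run spike-in QC.

At 3 kb/min for 60 min a perturbation reaches 180 kb into a gene body, so
only genes longer than 180 kb (plus the 500 bp terminal exclusion and a
1 kb minimum region) contribute invariant 3' segments.  The spike-in QC
flags samples whose Drosophila spike-in covers its 30 Mb transcriptome
less than 10-fold.
"""

from vsinorm import (
    GeneModel,
    length_threshold,
    select_invariant_regions,
    spike_in_coverage,
)

threshold = length_threshold(elongation_rate=3, time_point=60)
print(f"length threshold: {threshold} bp")

genes = [
    GeneModel("geneA", "tA", "chr1", 0, 200_000, "+"),       # 200 kb: kept
    GeneModel("geneB", "tB", "chr1", 300_000, 400_000, "+"),  # 100 kb: too short
    GeneModel("geneC", "tC", "chr2", 0, 250_000, "-"),        # 250 kb, minus strand
]
regions = select_invariant_regions(genes, threshold, end_exclusion=500, min_region=1000)
for r in regions:
    print(f"  {r.gene_id}: {r.chrom}:{r.start}-{r.end} ({r.strand}), {r.length} bp")
print(f"{len(regions)} of {len(genes)} genes contribute an invariant region")

print()
for bases in (21_000_000, 450_000_000):
    qc = spike_in_coverage(aligned_bases=bases)
    verdict = "PASS" if qc.passes_threshold else "FAIL"
    print(f"spike-in with {bases:,} aligned bases: {qc.coverage:.1f}X coverage -> {verdict}")
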