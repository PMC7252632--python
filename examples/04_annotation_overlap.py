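"""Summarize promoter overlap with annotation tracks as Venn cells.

Predicted promoters gain plausibility when they coincide with ESTs,
CpG islands or common SNPs; this example computes the 7-cell Venn
breakdown for a toy call set.
"""

from chromsig.annotate import AnnotationSet, overlap_summary
from chromsig.scan import PutativePromoter, SignificanceRegion, SignificanceWindow


def promoter(start, end, cluster):
    w = SignificanceWindow("chr1", start, end, cluster, 0.9)
    region = SignificanceRegion("chr1", start, end, cluster, 0.9, w, w, 1)
    return PutativePromoter("chr1", start, end, cluster, [region])


promoters = [promoter(1_000, 11_000, 1), promoter(50_000, 60_000, 1),
             promoter(90_000, 100_000, 2), promoter(150_000, 160_000, 3)]

est = AnnotationSet.from_intervals("EST", [("chr1", 5_000, 55_000)])
cpg = AnnotationSet.from_intervals("CpG", [("chr1", 52_000, 53_000)])
snp = AnnotationSet.from_intervals("SNP", [("chr1", 95_000, 95_000)])

summary = overlap_summary(promoters, [est, cpg, snp])
print(summary.to_frame().to_string(index=False))
print(f"\n{summary.pct_overlapping:.1f}% of promoters overlap >= 1 annotation")
# Each promoter lands in exactly one Venn cell; "none" counts the calls
# without any supporting annotation.
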