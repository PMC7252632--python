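"""The window-merging, assignment and shortening rules on known inputs.

Builds the runs of overlapping 10 kb significance windows from three
clusters, merges them into significance regions, groups the regions
into putative promoters, and applies the optional shortening rule.
"""

from chromsig.scan import SignificanceWindow, group_and_assign, merge_windows, shorten_region


def windows(first_start, last_start, cluster, r):
    return [SignificanceWindow("chr1", s, s + 9999, cluster, r)
            for s in range(first_start, last_start + 1, 100)]


ws = (windows(9701, 22301, 1, 0.9)      # cluster 1 run
      + windows(22101, 26301, 2, 0.8)   # cluster 2 run, overlapping it
      + windows(25801, 30001, 3, 0.7)   # cluster 3 run, overlapping both
      + windows(66301, 67801, 3, 0.7))  # an isolated cluster 3 run

regions = [r for k in (1, 2, 3) for r in merge_windows(ws, cluster_id=k)]
for r in regions:
    print(f"cluster {r.cluster_id} region {r.start}-{r.end} ({r.n_windows} windows)")

promoters = sorted(group_and_assign(regions), key=lambda p: p.start)
for p in promoters:
    print(f"putative promoter {p.start}-{p.end} -> cluster {p.cluster_id} "
          f"(evidence from {len(p.evidence)} region(s))")

short = shorten_region(promoters[0], mode="both")
print(f"shortened by half a window at each end: {short.start}-{short.end}")
# The first promoter is the union 9701-40000 assigned to cluster 1 (its
# run holds the largest correlation); shortening trims 5 kb per side.
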