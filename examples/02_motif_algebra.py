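"""The generalized-letter algebra behind motif merging.

Letters denote base sets (R = {A,G}, N = {A,C,G,T}, ...); merging two motifs
takes the site-wise union, and distances are site-wise Jaccard distances
minimized over the direct and antisense orientation.
"""

from pmf import (
    Motif,
    members,
    merge_letters,
    merge_motifs,
    motif_covers,
    motif_distance,
    specificity,
)

print("members(R) =", sorted(members("R")), " merge(A,G) =", merge_letters("A", "G"))

m1, m2 = Motif("ACGTGA"), Motif("GCGTGA")
d, anti = motif_distance(m1, m2)
print(f"distance({m1}, {m2}) = {d:.2f} (antisense={anti})")

merged = merge_motifs(m1, m2, anti)
print(f"merged motif: {merged}  covers {sorted(merged.covered)}")
print("covers GCGTGA:", motif_covers(merged, "GCGTGA"))

# specificity: 0 for all-N, 0.75 for a fully specified motif
for s in ("NNNNNN", "RCGTGA", "ACGTGA"):
    print(f"specificity({s}) = {specificity(s):.3f}")
print("a motif loses specificity as it degenerates toward all-N;",
      "ranking trades that against class association, (1 - p) + specificity.")
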