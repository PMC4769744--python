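"""Build a normalized canonical k-mer profile from a handful of reads.

Each read's k-mer counts are weighted by 1/length, pooled with their reverse
complements onto the lexicographically smaller (canonical) form, summed over
reads and divided by the number of reads — so profiles are strand-invariant
and insensitive to sequencing depth.
"""

from pmf import SampleReads, build_profile_matrix, build_sample_profile

sample = SampleReads(
    "demo",
    [
        ("r1", "ACGTACGTAC"),
        ("r2", "GTACGTACGT"),  # the reverse complement of r1
        ("r3", "ACGTNACGTA"),  # the N only drops the windows containing it
    ],
)

profile = build_sample_profile(sample, k_range=[2, 3])
print("canonical 2/3-mer profile of one sample:")
for kmer, value in sorted(profile.items()):
    print(f"  {kmer:4s} {value:.4f}")

matrix = build_profile_matrix([sample], labels=[0], k_range=[2, 3])
print(f"\nmatrix: {matrix.n_features} features x {matrix.n_samples} sample")
print("r1 and its reverse complement r2 contribute identically:",
      "every value reflects both strands pooled onto one canonical k-mer.")
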