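"""Alignment-free k-mer profiling of per-sample 16S rRNA read collections.

A sample's profile is built by sliding windows of width k = 2..6 over every
read, pooling each k-mer with its reverse complement onto a canonical form
(the lexicographically smaller of the two), weighting each read's counts by
the reciprocal of the read length, and dividing by the number of reads in the
sample.  Profiles over many samples are assembled into a features-by-samples
matrix with integer class labels, serialized as a TSV whose last row holds
the labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SampleReads",
    "KmerProfileMatrix",
    "count_kmers",
    "canonicalize",
    "build_sample_profile",
    "build_profile_matrix",
    "filter_zero_variance",
    "read_profile_table",
    "write_profile_table",
    "read_fasta_sample",
]

_COMP = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

LABEL_ROW = "__class__"


@dataclass
class SampleReads:
    """Reads of one sample: ``(read_id, sequence)`` pairs over {A,C,G,T,...}.

    Characters outside ACGT do not invalidate a read; only the k-mer windows
    containing them are skipped.
    """

    sample_id: str
    reads: list[tuple[str, str]]


@dataclass
class KmerProfileMatrix:
    """Normalized canonical k-mer counts, features x samples, with labels.

    ``values`` is a DataFrame whose index holds canonical k-mer strings and
    whose columns are sample ids; ``labels`` is an integer Series aligned with
    the columns.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if not self.values.columns.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.columns)
            if self.labels.isna().any():
                raise ValueError("labels do not cover all samples")
        self.labels = self.labels.astype(int)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature_lengths(self) -> pd.Series:
        return self.values.index.str.len()

    def subset(self, feature_names: Sequence[str]) -> "KmerProfileMatrix":
        return KmerProfileMatrix(self.values.loc[list(feature_names)], self.labels)


def count_kmers(sequence: str, k: int) -> dict[str, int]:
    """Sliding-window k-mer counts; windows with non-ACGT characters skipped.

    A sequence shorter than k yields an empty map.
    """
    if not 2 <= k <= 6:
        raise ValueError(f"k must be in 2..6, got {k}")
    seq = sequence.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if _VALID.issuperset(window):
            counts[window] = counts.get(window, 0) + 1
    return counts


def canonicalize(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    if not _VALID.issuperset(kmer):
        raise ValueError(f"invalid characters in k-mer {kmer!r}")
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def build_sample_profile(
    sample: SampleReads, k_range: Iterable[int] = range(2, 7)
) -> dict[str, float]:
    """Normalized canonical k-mer profile of one sample.

    Per read, raw window counts are weighted by 1/len(read); counts of a
    k-mer and its reverse complement pool onto the canonical form; weighted
    counts are summed over reads and divided by the number of reads.
    """
    if not sample.reads:
        raise ValueError(f"sample {sample.sample_id!r} has no reads")
    ks = sorted(set(k_range))
    profile: dict[str, float] = {}
    for _, seq in sample.reads:
        w = 1.0 / len(seq)
        for k in ks:
            for kmer, c in count_kmers(seq, k).items():
                canon = canonicalize(kmer)
                profile[canon] = profile.get(canon, 0.0) + c * w
    n = len(sample.reads)
    return {kmer: v / n for kmer, v in profile.items()}


def build_profile_matrix(
    samples: Sequence[SampleReads],
    labels: Sequence[int],
    k_range: Iterable[int] = range(2, 7),
) -> KmerProfileMatrix:
    """Assemble per-sample profiles into a features-by-samples matrix.

    Rows are the union of all canonical k-mers seen in any sample (missing
    entries zero), ordered by length then lexicographically.
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    if len(samples) != len(labels):
        raise ValueError(f"{len(samples)} samples but {len(labels)} labels")
    cols = {s.sample_id: build_sample_profile(s, k_range) for s in samples}
    df = pd.DataFrame(cols).fillna(0.0)
    df = df.reindex(sorted(df.index, key=lambda f: (len(f), f)))
    lab = pd.Series(list(labels), index=[s.sample_id for s in samples])
    return KmerProfileMatrix(df, lab)


def filter_zero_variance(matrix: KmerProfileMatrix) -> KmerProfileMatrix:
    """Drop features whose value is identical across all samples.

    Row order of the survivors is preserved; an empty result is an error.
    """
    v = matrix.values.to_numpy()
    keep = ~np.all(v == v[:, [0]], axis=1)
    if not keep.any():
        raise ValueError("all features have zero variance; nothing to learn from")
    return KmerProfileMatrix(matrix.values.loc[keep], matrix.labels)


def write_profile_table(matrix: KmerProfileMatrix, path: str | Path) -> None:
    """Write the profile as TSV: header = sample ids, last row = class labels."""
    out = matrix.values.copy()
    out.loc[LABEL_ROW] = matrix.labels.to_numpy()
    out.to_csv(path, sep="\t", index_label="feature")


def read_profile_table(path: str | Path) -> KmerProfileMatrix:
    """Read a TSV profile table whose final row holds integer class labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] < 2:
        raise ValueError("profile table needs at least one feature row and a label row")
    label_row = df.index[-1]
    labels_raw = df.loc[label_row]
    values = df.iloc[:-1]
    if values.index.has_duplicates:
        raise ValueError("duplicate feature names in profile table")
    try:
        values = values.astype(float)
        labels = labels_raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in profile table: {exc}") from None
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("label row is not integer-valued; is the label row missing?")
    values.index.name = None
    return KmerProfileMatrix(values, labels.round().astype(int))


def read_fasta_sample(path: str | Path, sample_id: str | None = None) -> SampleReads:
    """Load one sample's reads from a multi-FASTA file."""
    p = Path(path)
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(p), "fasta")]
    if not reads:
        raise ValueError(f"no reads in {p}")
    return SampleReads(sample_id or p.stem, reads)


def read_fasta_dir(
    fasta_dir: str | Path, labels: Mapping[str, int], k_range: Iterable[int] = range(2, 7)
) -> KmerProfileMatrix:
    """Build a profile matrix from a directory of per-sample FASTA files.

    ``labels`` maps sample id (FASTA stem) to class code; files without a
    label entry are an error.
    """
    paths = sorted(Path(fasta_dir).glob("*.fa")) + sorted(Path(fasta_dir).glob("*.fasta"))
    if not paths:
        raise ValueError(f"no FASTA files in {fasta_dir}")
    samples = [read_fasta_sample(p) for p in paths]
    missing = [s.sample_id for s in samples if s.sample_id not in labels]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    return build_profile_matrix(samples, [labels[s.sample_id] for s in samples], k_range)
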