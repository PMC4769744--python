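"""Synthetic read sets and profile matrices with known planted structure.

``generate_reads`` emulates the situation the pipeline targets: per-class
collections of short 16S-like reads in which concrete instances of a planted
degenerate motif occur at class-dependent Poisson rates against an i.i.d.
background.  ``generate_profile_matrix`` skips read simulation and directly
synthesizes a labelled profile matrix (log-normal background with additive
class shifts on designated features) for fast unit tests of the downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import members
from .profiles import KmerProfileMatrix, SampleReads, canonicalize

__all__ = ["PlantSpec", "generate_reads", "generate_profile_matrix", "write_fasta_dir"]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class PlantSpec:
    """Conditions of a planted-motif read simulation.

    ``rates`` is the expected number of planted motif instances per read, one
    entry per class; instances never overlap within a read.  Background bases
    are i.i.d. from ``base_freqs`` (uniform by default; 16S data are GC-skewed,
    so a skew can be supplied).
    """

    motif: str
    rates: Sequence[float]
    read_length: int = 150
    reads_per_sample: int = 200
    samples_per_class: Sequence[int] = (20, 20)
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.samples_per_class):
            raise ValueError("need one rate per class")
        if any(r < 0 or not np.isfinite(r) for r in self.rates):
            raise ValueError("rates must be finite and >= 0")
        if len(self.motif) > self.read_length:
            raise ValueError("motif longer than read")
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or not np.isclose(f.sum(), 1.0):
            raise ValueError("base_freqs must be 4 probabilities summing to 1")


def _motif_instances(motif: str) -> list[str]:
    """All concrete k-mers matched by the motif (direct orientation)."""
    pools = [sorted(members(s)) for s in motif]
    out = [""]
    for pool in pools:
        out = [pre + b for pre in out for b in pool]
    return out


def generate_reads(spec: PlantSpec) -> tuple[list[SampleReads], list[int]]:
    """Simulate per-sample read sets with class-dependent planted motif rates.

    Each planted instance is a uniformly chosen concrete match of the motif,
    written on a random strand at a random position; placements within a read
    are rejected if they would overlap an earlier instance.  Deterministic
    for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    instances = _motif_instances(spec.motif)
    k = len(spec.motif)
    samples: list[SampleReads] = []
    labels: list[int] = []
    for cls, (n_samples, rate) in enumerate(zip(spec.samples_per_class, spec.rates)):
        for s in range(n_samples):
            sid = f"class{cls}_s{s:03d}"
            reads = []
            for r in range(spec.reads_per_sample):
                seq = rng.choice(_BASES, size=spec.read_length, p=np.asarray(spec.base_freqs))
                seq = list(seq)
                n_plant = rng.poisson(rate)
                placed: list[tuple[int, int]] = []
                for _ in range(n_plant):
                    for _try in range(50):  # rejection placement, no overlaps
                        pos = int(rng.integers(0, spec.read_length - k + 1))
                        if all(pos + k <= a or pos >= b for a, b in placed):
                            break
                    else:
                        continue
                    inst = instances[int(rng.integers(len(instances)))]
                    if rng.integers(2):
                        inst = inst.translate(_COMP)[::-1]
                    seq[pos : pos + k] = list(inst)
                    placed.append((pos, pos + k))
                reads.append((f"{sid}_r{r:04d}", "".join(seq)))
            samples.append(SampleReads(sid, reads))
            labels.append(cls)
    return samples, labels


def planted_canonical_kmers(motif: str) -> frozenset[str]:
    """Canonical forms of every concrete instance of the planted motif."""
    return frozenset(canonicalize(x) for x in _motif_instances(motif))


def planted_signal_kmers(motif: str, k_range=range(2, 7)) -> frozenset[str]:
    """Canonical sub-k-mers of the motif's instances, over all lengths in k_range.

    These are the features whose counts carry planted class signal: every
    window that lies inside a planted instance.
    """
    out: set[str] = set()
    for inst in _motif_instances(motif):
        for k in k_range:
            for i in range(len(inst) - k + 1):
                out.add(canonicalize(inst[i : i + k]))
    return frozenset(out)


def generate_profile_matrix(
    n_features: int,
    n_samples_per_class: Sequence[int] = (20, 20),
    effect_features: int = 0,
    effect_size: float = 1.0,
    k: int | None = 4,
    seed: int = 0,
) -> KmerProfileMatrix:
    """Directly synthesize a labelled profile matrix, bypassing read simulation.

    Features are named by distinct canonical ``k``-mers (``k=None`` pools
    lengths 2 upward until enough names exist); the first ``effect_features``
    rows get an additive shift of ``effect_size`` (times the background
    scale) in every class after the first, on top of a log-normal background.
    """
    rng = np.random.default_rng(seed)
    if k is not None:
        names = _distinct_canonical_kmers(n_features, k)
    else:
        names = []
        for kk in range(2, 7):
            pool = _distinct_canonical_kmers(None, kk)
            names.extend(pool[: n_features - len(names)])
            if len(names) >= n_features:
                break
        if len(names) < n_features:
            raise ValueError(f"cannot produce {n_features} distinct canonical k-mers")
    n_total = int(np.sum(n_samples_per_class))
    values = rng.lognormal(mean=0.0, sigma=0.5, size=(n_features, n_total))
    labels = np.repeat(np.arange(len(n_samples_per_class)), n_samples_per_class)
    for cls in range(1, len(n_samples_per_class)):
        values[:effect_features, labels == cls] += effect_size * cls
    cols = [f"s{i:03d}" for i in range(n_total)]
    df = pd.DataFrame(values, index=names, columns=cols)
    return KmerProfileMatrix(df, pd.Series(labels, index=cols))


def _distinct_canonical_kmers(n: int | None, k: int) -> list[str]:
    seen: list[str] = []
    have = set()
    # enumerate k-mers in lexicographic order, keeping canonical representatives
    def rec(prefix: str) -> None:
        if n is not None and len(seen) >= n:
            return
        if len(prefix) == k:
            c = canonicalize(prefix)
            if c not in have:
                have.add(c)
                seen.append(c)
            return
        for b in "ACGT":
            rec(prefix + b)

    rec("")
    if n is not None and len(seen) < n:
        raise ValueError(f"cannot produce {n} distinct canonical {k}-mers")
    return seen


def write_fasta_dir(
    samples: Sequence[SampleReads], labels: Sequence[int], out_dir: str | Path
) -> None:
    """Write one FASTA per sample plus a labels.tsv mapping sample id to class."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        with open(out / f"{s.sample_id}.fa", "w") as fh:
            for rid, seq in s.reads:
                fh.write(f">{rid}\n{seq}\n")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("sample\tlabel\n")
        for s, lab in zip(samples, labels):
            fh.write(f"{s.sample_id}\t{lab}\n")
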