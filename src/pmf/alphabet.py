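"""Algebra of the 15-letter generalized (IUPAC) nucleotide alphabet.

Each generalized letter denotes a nonempty subset of {A, C, G, T}; merging two
letters takes the union of their member sets, and the antisense complement of
a letter is the letter whose members are the base complements of its members.
Motifs are fixed-length strings of generalized letters; the distance between
two motifs is the sum over sites of the Jaccard distance between member sets,
minimized over the direct and reverse-complement orientation of the second
motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "ALPHABET",
    "members",
    "symbol_for",
    "merge_letters",
    "complement_letter",
    "site_difference",
    "Motif",
    "reverse_complement_motif",
    "motif_distance",
    "merge_motifs",
    "motif_covers",
]

# Member sets of the generalized letters.  D is the standard IUPAC {A,G,T}
# (the complement of H), not a duplicate of B.
_MEMBERS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "S": frozenset("CG"),
    "H": frozenset("ACT"),
    "B": frozenset("CGT"),
    "V": frozenset("ACG"),
    "D": frozenset("AGT"),
    "N": frozenset("ACGT"),
}

_SYMBOL: dict[frozenset[str], str] = {v: k for k, v in _MEMBERS.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ALPHABET: tuple[str, ...] = tuple(_MEMBERS)


def members(symbol: str) -> frozenset[str]:
    """Member bases of a generalized letter, e.g. ``members("R") == {A, G}``."""
    try:
        return _MEMBERS[symbol]
    except KeyError:
        raise ValueError(f"unknown generalized letter: {symbol!r}") from None


def symbol_for(member_set: frozenset[str]) -> str:
    """Inverse of :func:`members`: the unique letter for a nonempty base set."""
    try:
        return _SYMBOL[frozenset(member_set)]
    except KeyError:
        raise ValueError(f"no generalized letter for member set {set(member_set)}") from None


@lru_cache(maxsize=None)
def merge_letters(a: str, b: str) -> str:
    """Letter whose member set is the union of the members of ``a`` and ``b``."""
    return _SYMBOL[members(a) | members(b)]


@lru_cache(maxsize=None)
def complement_letter(symbol: str) -> str:
    """Antisense complement: the letter of the base-complemented member set."""
    return _SYMBOL[frozenset(_BASE_COMPLEMENT[m] for m in members(symbol))]


@lru_cache(maxsize=None)
def site_difference(a: str, b: str) -> float:
    """Jaccard distance between two letters' member sets: 1 - |a∩b| / |a∪b|.

    0 for identical letters, 1 for disjoint ones (e.g. A vs T).
    """
    sa, sb = members(a), members(b)
    return 1.0 - len(sa & sb) / len(sa | sb)


@dataclass(frozen=True)
class Motif:
    """A fixed-length string over the generalized alphabet.

    ``covered`` carries the canonical k-mers this motif replaced during
    agglomeration; each of them is matched by the motif in one orientation.
    """

    sites: str
    covered: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for s in self.sites:
            if s not in _MEMBERS:
                raise ValueError(f"invalid generalized letter {s!r} in motif {self.sites!r}")
        if not self.sites:
            raise ValueError("motif must be nonempty")
        if not self.covered:
            object.__setattr__(self, "covered", frozenset({self.sites}))

    def __len__(self) -> int:
        return len(self.sites)

    def __str__(self) -> str:
        return self.sites

    @property
    def is_all_n(self) -> bool:
        return set(self.sites) == {"N"}

    def member_sizes(self) -> list[int]:
        return [len(_MEMBERS[s]) for s in self.sites]


def _rc_string(sites: str) -> str:
    return "".join(complement_letter(s) for s in reversed(sites))


def reverse_complement_motif(m: Motif) -> Motif:
    """Reverse the site order and complement every letter (an involution)."""
    return Motif(_rc_string(m.sites), m.covered)


def motif_distance(m1: Motif | str, m2: Motif | str) -> tuple[float, bool]:
    """Distance between equal-length motifs and the orientation that attains it.

    Returns ``(distance, use_antisense)`` where the distance is the smaller of
    the site-wise Jaccard distance sum against ``m2`` and against its reverse
    complement.  Ties go to the direct orientation.
    """
    s1 = m1.sites if isinstance(m1, Motif) else m1
    s2 = m2.sites if isinstance(m2, Motif) else m2
    if len(s1) != len(s2):
        raise ValueError(f"motif length mismatch: {len(s1)} vs {len(s2)}")
    direct = sum(site_difference(a, b) for a, b in zip(s1, s2))
    anti = sum(site_difference(a, b) for a, b in zip(s1, _rc_string(s2)))
    if anti < direct:
        return anti, True
    return direct, False


def merge_motifs(m1: Motif, m2: Motif, use_antisense: bool = False) -> Motif:
    """Site-wise union merge of ``m1`` with ``m2`` (or its reverse complement).

    The merged motif covers the union of both motifs' covered k-mer sets.
    """
    s2 = _rc_string(m2.sites) if use_antisense else m2.sites
    if len(m1.sites) != len(s2):
        raise ValueError("motif length mismatch")
    merged = "".join(merge_letters(a, b) for a, b in zip(m1.sites, s2))
    return Motif(merged, m1.covered | m2.covered)


def motif_covers(m: Motif | str, kmer: str) -> bool:
    """True iff the motif matches ``kmer`` on either strand.

    A match requires every base of the k-mer to be a member of the
    corresponding site's set.
    """
    sites = m.sites if isinstance(m, Motif) else m

    def _direct(s: str, x: str) -> bool:
        return len(s) == len(x) and all(b in _MEMBERS[a] for a, b in zip(s, x))

    rc = "".join(_BASE_COMPLEMENT[b] for b in reversed(kmer))
    return _direct(sites, kmer) or _direct(sites, rc)
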