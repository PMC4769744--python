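"""Cross-length ranking of generalized motifs by specificity and class association.

A motif's specificity averages, over its sites, one minus the member-set size
divided by four: 0 for an all-N motif, 0.75 for a fully specified one.  Motifs
are sorted in descending order of (1 - p) + specificity, where p is the
Kruskal-Wallis p-value of the motif's merged profile in the selected model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import Motif
from .baselines import kruskal_wallis

__all__ = ["RankedMotif", "specificity", "motif_score", "sort_motifs", "rank_model_motifs"]


@dataclass(frozen=True)
class RankedMotif:
    motif: Motif
    p_value: float
    specificity: float
    score: float


def specificity(m: Motif | str) -> float:
    """Mean over sites of (1 - member_count/4); in [0, 0.75]."""
    motif = m if isinstance(m, Motif) else Motif(m)
    sizes = motif.member_sizes()
    return sum(1.0 - x / 4.0 for x in sizes) / len(sizes)


def motif_score(p_value: float, spec: float) -> float:
    """(1 - p) + specificity; higher is better, maximum 1.75."""
    return (1.0 - p_value) + spec


def sort_motifs(motifs: list[RankedMotif]) -> list[RankedMotif]:
    """Descending by score; ties by smaller p-value, then motif string."""
    return sorted(motifs, key=lambda r: (-r.score, r.p_value, r.motif.sites))


def rank_model_motifs(profiles: pd.DataFrame, labels: np.ndarray) -> list[RankedMotif]:
    """Score every feature of a model snapshot (rows = motif strings).

    The p-value is the Kruskal-Wallis p of the motif's merged profile across
    the labelled samples.
    """
    y = np.asarray(labels)
    ranked = []
    for pos in range(len(profiles)):
        name = str(profiles.index[pos])
        _, p = kruskal_wallis(profiles.iloc[pos].to_numpy(dtype=float), y)
        s = specificity(name)
        ranked.append(RankedMotif(Motif(name), p, s, motif_score(p, s)))
    return sort_motifs(ranked)
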