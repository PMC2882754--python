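"""Motif presence and co-occurrence census over a set of cytoplasmic tails.

The census answers, for a tail database and a motif registry: how many
tails carry at least one copy of each motif (the *singles*), and how
many carry at least one copy of each of two motifs (the symmetric
*pairs* matrix). Copy number never inflates counts — a tail with five
YXXΦ windows contributes one to singles[YXXΦ].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import MotifPattern, has_motif

__all__ = [
    "CensusTable",
    "UndefinedOverlapError",
    "run_census",
    "overlap_fraction",
    "any_of_overlap",
    "no_signal_fraction",
    "format_report",
]


class UndefinedOverlapError(ZeroDivisionError):
    """Overlap fraction requested against a motif present in zero tails."""


@dataclass(frozen=True)
class CensusTable:
    """Per-motif presence counts and pairwise co-occurrence counts.

    ``singles[a]`` is the number of tails with ≥1 copy of motif *a*;
    ``pairs[a][b]`` the number of tails with ≥1 copy of both *a* and
    *b*. The matrix is symmetric and its diagonal equals ``singles``.
    """

    motifs: tuple
    n_tails: int
    singles: Mapping[str, int]
    pairs: Mapping[str, Mapping[str, int]]

    def __post_init__(self):
        for a in self.motifs:
            if self.singles[a] > self.n_tails:
                raise ValueError(f"singles[{a}] exceeds n_tails")
            if self.pairs[a][a] != self.singles[a]:
                raise ValueError(f"pairs[{a}][{a}] != singles[{a}]")
            for b in self.motifs:
                if self.pairs[a][b] != self.pairs[b][a]:
                    raise ValueError(f"pairs not symmetric at ({a}, {b})")
                if self.pairs[a][b] > min(self.singles[a], self.singles[b]):
                    raise ValueError(f"pairs[{a}][{b}] exceeds min of singles")

    def to_frame(self) -> pd.DataFrame:
        """Motif × motif count matrix (diagonal = singles)."""
        data = [[self.pairs[a][b] for b in self.motifs] for a in self.motifs]
        return pd.DataFrame(data, index=list(self.motifs), columns=list(self.motifs))


def run_census(tails: Sequence, motifs: Mapping[str, MotifPattern]) -> CensusTable:
    """Count per-motif presence and pairwise co-occurrence over ``tails``.

    Presence is per-tail ("at least one copy"), so the diagonal of the
    pair matrix equals the singles vector by construction.
    """
    if not motifs:
        raise ValueError("motif registry is empty")
    names = tuple(motifs)
    tail_list = list(tails)
    # boolean presence matrix: tails × motifs
    present = np.zeros((len(tail_list), len(names)), dtype=bool)
    for j, nm in enumerate(names):
        pat = motifs[nm]
        for i, tail in enumerate(tail_list):
            present[i, j] = has_motif(tail, pat)
    counts = present.astype(np.int64)
    pair_counts = counts.T @ counts  # symmetric, diagonal = singles
    singles = {nm: int(pair_counts[j, j]) for j, nm in enumerate(names)}
    pairs = {
        a: {b: int(pair_counts[i, j]) for j, b in enumerate(names)}
        for i, a in enumerate(names)
    }
    return CensusTable(motifs=names, n_tails=len(tail_list), singles=singles, pairs=pairs)


def overlap_fraction(table: CensusTable, a: str, b: str) -> float:
    """Fraction of motif-*a* tails that also carry motif *b*.

    Undefined when no tail carries *a*; signalled with
    :class:`UndefinedOverlapError` rather than returning NaN.
    """
    if table.singles[a] == 0:
        raise UndefinedOverlapError(
            f"overlap fraction undefined: no tail carries {a!r}"
        )
    return table.pairs[a][b] / table.singles[a]


def any_of_overlap(
    tails: Sequence,
    anchor_motif: MotifPattern,
    others: Iterable[MotifPattern],
) -> tuple:
    """(tails with the anchor motif, those among them with ≥1 of ``others``).

    E.g. with a C-terminal GGA-binding motif as anchor and the classical
    internalization signals as ``others``, the second count says how many
    GGA-motif tails also carry an internalization signal.
    """
    others = list(others)
    n_anchor = 0
    n_with_other = 0
    for tail in tails:
        if not has_motif(tail, anchor_motif):
            continue
        n_anchor += 1
        if any(has_motif(tail, o) for o in others):
            n_with_other += 1
    return n_anchor, n_with_other


def no_signal_fraction(tails: Sequence, signal_set: Iterable[MotifPattern]) -> float:
    """Fraction of tails carrying none of the given signals.

    With the classical motif set this measures how much of a tail
    database is unexplained by known internalization signals. The empty
    signal set trivially gives 1.0; an empty tail set is an error.
    """
    tail_list = list(tails)
    if not tail_list:
        raise ValueError("no_signal_fraction needs at least one tail")
    signals = list(signal_set)
    n_clean = sum(
        1 for t in tail_list if not any(has_motif(t, s) for s in signals)
    )
    return n_clean / len(tail_list)


def format_report(table: CensusTable) -> str:
    """Human-readable census summary with whole-percent frequencies."""
    lines = [f"tails scanned: {table.n_tails}", ""]
    lines.append("motif presence (tails with >=1 copy):")
    for nm in table.motifs:
        s = table.singles[nm]
        pct = 100.0 * s / table.n_tails if table.n_tails else 0.0
        lines.append(f"  {nm}: {s} ({pct:.0f}%)")
    lines.append("")
    lines.append("pairwise co-occurrence (tails with both motifs):")
    for i, a in enumerate(table.motifs):
        for b in table.motifs[i + 1 :]:
            lines.append(f"  {a} & {b}: {table.pairs[a][b]}")
    return "\n".join(lines)
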