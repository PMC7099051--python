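"""Per-alignment summary statistics: length, parsimony-informative content,
missing data — the quantities an alignment summariser reports per region.

A column is parsimony informative when, counting only the unambiguous states
A/C/G/T, at least two distinct states each occur in at least two sequences.
Gaps, ``?``, ``N`` and partial IUPAC ambiguity codes never count as states.

The missing-data fraction counts cells in ``{-, ?, N}``; partial ambiguities
(R, Y, S, W, K, M, B, D, H, V) are *not* missing by default — they carry
partial information even though they are excluded from state counts. Pass
``ambiguous_as_missing=True`` to fold them into the missing set instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Alignment

__all__ = [
    "AlignmentStats",
    "is_parsimony_informative",
    "alignment_summary",
    "summarize_set",
    "MISSING",
    "STATES",
    "AMBIGUOUS",
]

STATES = ("A", "C", "G", "T")
MISSING = frozenset("-?N")
AMBIGUOUS = frozenset("RYSWKMBDHV")


@dataclass
class AlignmentStats:
    """Summary statistics for one locus alignment."""

    locus_id: str
    length: int
    n_taxa: int
    n_pic: int
    p_pic: float
    n_variable: int
    missing_frac: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "locus": self.locus_id,
            "length": self.length,
            "n_taxa": self.n_taxa,
            "n_pic": self.n_pic,
            "p_pic": self.p_pic,
            "n_variable": self.n_variable,
            "missing_frac": self.missing_frac,
        }


def is_parsimony_informative(column: Sequence[str]) -> bool:
    """True iff >=2 distinct unambiguous states each occur >=2 times.

    Characters outside {A,C,G,T} (case-insensitive) are ignored entirely.
    """
    counts: dict[str, int] = {}
    for ch in column:
        ch = ch.upper()
        if ch in ("A", "C", "G", "T"):
            counts[ch] = counts.get(ch, 0) + 1
    return sum(1 for v in counts.values() if v >= 2) >= 2


def _state_counts(arr: np.ndarray) -> np.ndarray:
    """(4, length) matrix of per-column A/C/G/T counts."""
    return np.stack([(arr == s.encode()).sum(axis=0) for s in STATES])


def alignment_summary(
    aln: Alignment, ambiguous_as_missing: bool = False
) -> AlignmentStats:
    """Column-wise summary of one alignment.

    A zero-length or zero-taxon alignment returns all-zero statistics with
    ``degenerate=True``.
    """
    if aln.length == 0 or aln.n_taxa == 0:
        return AlignmentStats(aln.locus_id, aln.length, aln.n_taxa, 0, 0.0, 0, 0.0,
                              degenerate=True)
    arr = aln.to_array()
    counts = _state_counts(arr)
    n_variable = int(((counts >= 1).sum(axis=0) >= 2).sum())
    n_pic = int(((counts >= 2).sum(axis=0) >= 2).sum())
    missing_set = MISSING | AMBIGUOUS if ambiguous_as_missing else MISSING
    missing = np.zeros(arr.shape, dtype=bool)
    for ch in missing_set:
        missing |= arr == ch.encode()
    return AlignmentStats(
        locus_id=aln.locus_id,
        length=aln.length,
        n_taxa=aln.n_taxa,
        n_pic=n_pic,
        p_pic=n_pic / aln.length,
        n_variable=n_variable,
        missing_frac=float(missing.mean()),
    )


def summarize_set(
    stats: Iterable[AlignmentStats],
    group_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-class mean/SD of length (bp), P_PIC (%) and missing data (%).

    One row per class plus an ``overall`` row. SD is the sample (n-1)
    standard deviation; single-member classes report SD 0 and are flagged.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("summarize_set needs a non-empty list of stats")
    df = pd.DataFrame(
        {
            "locus": [s.locus_id for s in stats],
            "length": [s.length for s in stats],
            "p_pic_pct": [100.0 * s.p_pic for s in stats],
            "missing_pct": [100.0 * s.missing_frac for s in stats],
        }
    )
    df["class"] = (
        df["locus"].map(lambda l: group_labels.get(l, "unassigned"))
        if group_labels
        else "all"
    )

    def _agg(sub: pd.DataFrame, name: str) -> dict:
        single = len(sub) == 1
        return {
            "class": name,
            "n_loci": len(sub),
            "length_mean": sub["length"].mean(),
            "length_sd": 0.0 if single else sub["length"].std(ddof=1),
            "p_pic_mean_pct": sub["p_pic_pct"].mean(),
            "p_pic_sd_pct": 0.0 if single else sub["p_pic_pct"].std(ddof=1),
            "missing_mean_pct": sub["missing_pct"].mean(),
            "missing_sd_pct": 0.0 if single else sub["missing_pct"].std(ddof=1),
            "single_member": single,
        }

    rows = [_agg(sub, name) for name, sub in df.groupby("class", sort=True)]
    rows.append(_agg(df, "overall"))
    return pd.DataFrame(rows)
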