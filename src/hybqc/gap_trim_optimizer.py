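"""Gap-threshold trimming with per-locus threshold optimisation.

Column trimming follows the classic gap-threshold (``-gt``) semantics: a
column survives when its fraction of non-gap characters is at least the
threshold. The optimiser sweeps a threshold grid, scores every trimmed
alignment by its proportion of parsimony-informative characters (P_PIC),
and picks — among thresholds whose data loss stays within the allowed
budget (default 30%) — the one maximising P_PIC, breaking ties toward the
lowest threshold (retain more sequence). Loci for which no admissible
threshold exists, or whose best P_PIC is zero, are marked for discard as
carrying too little signal relative to noise.

Data loss is residue-based by default: the fraction of non-gap characters
removed by trimming (``?`` and ``N`` count as present). A column-based
variant (fraction of columns removed) is available via ``loss_metric``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment_metrics import alignment_summary
from .core_io import Alignment

__all__ = ["TrimConfig", "TrimResult", "trim_at_threshold", "data_loss",
           "optimize_trim"]

DEFAULT_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class TrimConfig:
    """Threshold grid and data-loss budget for trimming optimisation."""

    thresholds: tuple[float, ...] = DEFAULT_GRID
    max_data_loss: float = 0.30
    loss_metric: str = "residues"  # or "columns"

    def __post_init__(self) -> None:
        ts = tuple(self.thresholds)
        if not ts:
            raise ValueError("threshold grid is empty")
        if any(not 0.0 <= t <= 1.0 for t in ts):
            raise ValueError("thresholds must lie in [0, 1]")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 <= self.max_data_loss <= 1.0:
            raise ValueError("max_data_loss must lie in [0, 1]")
        if self.loss_metric not in ("residues", "columns"):
            raise ValueError(f"unknown loss_metric: {self.loss_metric!r}")
        self.thresholds = ts


@dataclass
class TrimResult:
    """Outcome of the threshold sweep for one locus."""

    locus_id: str
    chosen_gt: float | None
    trimmed: Alignment
    data_loss: float
    #: threshold -> (p_pic, data_loss) for every swept threshold
    curve: dict[float, tuple[float, float]] = field(default_factory=dict)
    verdict: str = "keep"  # keep | discard


def _nongap_fracs(aln: Alignment) -> np.ndarray:
    arr = aln.to_array()
    return (arr != b"-").mean(axis=0)


def trim_at_threshold(aln: Alignment, gt: float) -> Alignment:
    """Keep exactly the columns whose non-gap fraction is >= ``gt``.

    Only ``-`` counts as a gap. ``gt=0`` keeps every column; ``gt=1`` keeps
    only gap-free columns. Rows and taxon order are untouched.
    """
    if not 0.0 <= gt <= 1.0:
        raise ValueError("gap threshold must lie in [0, 1]")
    if aln.length == 0 or aln.n_taxa == 0:
        return Alignment(aln.locus_id, list(aln.taxa), list(aln.rows))
    keep = np.nonzero(_nongap_fracs(aln) >= gt)[0]
    return aln.select_columns(keep)


def _residues(aln: Alignment) -> int:
    if aln.length == 0 or aln.n_taxa == 0:
        return 0
    return int((aln.to_array() != b"-").sum())


def data_loss(original: Alignment, trimmed: Alignment,
              metric: str = "residues") -> float:
    """Fraction of data removed by trimming; 0 for identity, 1 when empty."""
    if metric == "residues":
        denom = _residues(original)
        if denom == 0:
            raise ValueError(
                f"{original.locus_id}: data loss undefined — original "
                "alignment has no non-gap residues"
            )
        return 1.0 - _residues(trimmed) / denom
    if metric == "columns":
        if original.length == 0:
            raise ValueError(
                f"{original.locus_id}: data loss undefined — zero columns"
            )
        return 1.0 - trimmed.length / original.length
    raise ValueError(f"unknown loss metric: {metric!r}")


def optimize_trim(aln: Alignment, cfg: TrimConfig | None = None) -> TrimResult:
    """Sweep the threshold grid and choose the P_PIC-maximising trim.

    Among thresholds with data loss within ``cfg.max_data_loss``, the one
    with the highest trimmed P_PIC wins; ties go to the lowest threshold.
    The verdict is ``discard`` when no threshold is admissible or the best
    attainable P_PIC is zero. The full (p_pic, data_loss) curve over the
    grid is always returned.
    """
    cfg = cfg or TrimConfig()
    if aln.n_taxa < 4:
        warnings.warn(
            f"{aln.locus_id}: fewer than 4 taxa; no column can be "
            "parsimony-informative"
        )
    curve: dict[float, tuple[float, float]] = {}
    trims: dict[float, Alignment] = {}
    for gt in cfg.thresholds:
        trimmed = trim_at_threshold(aln, gt)
        loss = data_loss(aln, trimmed, metric=cfg.loss_metric)
        p = alignment_summary(trimmed).p_pic if trimmed.length else 0.0
        curve[gt] = (p, loss)
        trims[gt] = trimmed

    admissible = [gt for gt in cfg.thresholds
                  if curve[gt][1] <= cfg.max_data_loss]
    if not admissible:
        return TrimResult(aln.locus_id, None, Alignment(aln.locus_id, [], []),
                          1.0, curve, verdict="discard")
    # max p_pic, ties -> lowest gt (grid is sorted ascending)
    best = max(admissible, key=lambda gt: (curve[gt][0], -gt))
    if curve[best][0] == 0.0:
        return TrimResult(aln.locus_id, None, trims[best], curve[best][1],
                          curve, verdict="discard")
    return TrimResult(aln.locus_id, best, trims[best], curve[best][1], curve,
                      verdict="keep")
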