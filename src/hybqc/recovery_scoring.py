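"""Capture-success metrics and the composite coverage score.

Capture success for one (accession, locus) cell is the proportion of the
target reference length recovered, capped at 1. The composite coverage
score for an accession over m loci multiplies three components:

* representativeness r — fraction of loci with any sequence recovered;
* completeness c — mean capture success over the *recovered* loci
  (representativeness already penalises absence; averaging over all loci
  would double-count missingness — that variant is available via
  ``completeness="total"``);
* evenness e — Pielou evenness H'/ln(m) of the recovery distribution
  across loci: H' is the Shannon entropy of the normalised capture
  fractions (not raw recovered lengths, so that fully recovering loci of
  unequal size still counts as perfectly even); 0 when at most one locus
  is recovered, and 1 in the degenerate m=1 case when that locus is
  recovered.

The same definition applied down the other axis scores loci over
accessions. Accessions scoring below a cutoff (default 0.5) are dropped
before phylogenomic analysis.

The age/tissue effect report regresses per-accession mean capture success
on collection year (herbarium specimens only; OLS, F-test on 1 and n-2 df)
and contrasts herbarium against DNA-bank/silica material with a Welch
two-sample t-test (Welch–Satterthwaite df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_io import RecoveryMatrix

__all__ = [
    "CoverageScore",
    "EffectReport",
    "capture_success",
    "capture_success_matrix",
    "coverage_scores",
    "filter_by_score",
    "age_effect_report",
]


@dataclass
class CoverageScore:
    entity_id: str
    representativeness: float
    completeness: float
    evenness: float
    score: float


@dataclass
class EffectReport:
    """OLS age effect (herbarium) and Welch contrast vs other material."""

    slope: float
    f_stat: float
    df: int
    r_squared: float
    p_value: float
    t_stat: float | None = None
    welch_df: float | None = None
    t_p_value: float | None = None


def capture_success(recovered_length: float, target_length: float) -> float:
    """Proportion of the target reference recovered, capped at 1."""
    if target_length <= 0:
        raise ValueError("target_length must be > 0")
    if recovered_length > target_length:
        warnings.warn(
            f"recovered length {recovered_length} exceeds target "
            f"{target_length}; capping capture success at 1"
        )
        return 1.0
    return recovered_length / target_length


def capture_success_matrix(m: RecoveryMatrix) -> np.ndarray:
    """(n_accessions, n_loci) capture-success fractions, capped at 1."""
    targets = m.target_length[m.recovered.columns].values
    return np.minimum(m.recovered.values / targets, 1.0)


def _score_rows(
    ids: list[str], frac: np.ndarray, recovered: np.ndarray, completeness: str
) -> list[CoverageScore]:
    out = []
    n_items = frac.shape[1]
    for i, ident in enumerate(ids):
        present = recovered[i] > 0
        k = int(present.sum())
        r = k / n_items if n_items else 0.0
        if k == 0:
            out.append(CoverageScore(ident, 0.0, 0.0, 0.0, 0.0))
            continue
        if completeness == "recovered":
            c = float(frac[i, present].mean())
        elif completeness == "total":
            c = float(frac[i].mean())
        else:
            raise ValueError(f"unknown completeness mode: {completeness!r}")
        if n_items == 1:
            e = 1.0
        elif k <= 1:
            e = 0.0
        else:
            p = frac[i, present] / frac[i, present].sum()
            h = float(-(p * np.log(p)).sum())
            e = h / np.log(n_items)
        out.append(CoverageScore(ident, r, c, e, r * c * e))
    return out


def coverage_scores(
    m: RecoveryMatrix, axis: str = "accessions", completeness: str = "recovered"
) -> list[CoverageScore]:
    """Composite representativeness x completeness x evenness scores.

    ``axis="accessions"`` scores each accession over loci; ``axis="loci"``
    scores each locus over accessions (the transpose of the definition).
    """
    if m.recovered.empty:
        return []
    frac = capture_success_matrix(m)
    rec = m.recovered.values
    if axis == "accessions":
        return _score_rows(m.accessions, frac, rec, completeness)
    if axis == "loci":
        return _score_rows(m.loci, frac.T, rec.T, completeness)
    raise ValueError(f"unknown axis: {axis!r}")


def filter_by_score(
    scores: list[CoverageScore], cutoff: float = 0.5
) -> list[str]:
    """Identifiers with score >= cutoff (inclusive), input order preserved."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    return [s.entity_id for s in scores if s.score >= cutoff]


def age_effect_report(m: RecoveryMatrix) -> EffectReport:
    """Regression of capture success on specimen age plus a tissue contrast.

    Needs ``collection_year`` and ``source`` metadata. Herbarium accessions
    drive the OLS; the Welch t compares herbarium against the pooled
    DNA-bank/silica group (omitted with a warning if a group is empty).
    """
    if m.meta.empty or "collection_year" not in m.meta.columns:
        raise ValueError("age_effect_report needs collection_year metadata")
    frac = capture_success_matrix(m)
    mean_success = frac.mean(axis=1)
    meta = m.meta.reindex(m.accessions)
    source = meta.get("source")
    herb_mask = (
        (source == "herbarium").values
        if source is not None
        else np.ones(len(m.accessions), dtype=bool)
    )
    years = meta["collection_year"].values.astype(float)
    ok = herb_mask & ~np.isnan(years)
    if ok.sum() < 3:
        raise ValueError("need >=3 herbarium accessions with collection_year")
    x, y = years[ok], mean_success[ok]
    res = sps.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    f = (r2 / (1 - r2)) * (n - 2) if r2 < 1 else np.inf
    p = float(sps.f.sf(f, 1, n - 2)) if np.isfinite(f) else 0.0

    t_stat = welch_df = t_p = None
    if source is not None:
        other_mask = source.isin(["dna_bank", "silica"]).values
        a, b = mean_success[other_mask], mean_success[herb_mask]
        if len(a) >= 2 and len(b) >= 2:
            tt = sps.ttest_ind(a, b, equal_var=False)
            t_stat = float(tt.statistic)
            t_p = float(tt.pvalue)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            if va + vb > 0:
                welch_df = float(
                    (va / len(a) + vb / len(b)) ** 2
                    / (
                        (va / len(a)) ** 2 / (len(a) - 1)
                        + (vb / len(b)) ** 2 / (len(b) - 1)
                    )
                )
            else:
                welch_df = float(len(a) + len(b) - 2)
        else:
            warnings.warn("a tissue group is empty or too small; "
                          "contrast omitted")
    return EffectReport(
        slope=float(res.slope),
        f_stat=float(f),
        df=n - 2,
        r_squared=float(r2),
        p_value=p,
        t_stat=t_stat,
        welch_df=welch_df,
        t_p_value=t_p,
    )
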