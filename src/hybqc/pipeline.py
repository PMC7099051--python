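"""End-to-end QC orchestration.

Stages run in the order a capture-based phylogenomic study applies them:

1. **Coverage scoring** — composite per-accession scores from the recovery
   matrix; accessions below the cutoff (default 0.5) are dropped from all
   alignments and gene trees. This is the only accession-level filter;
   everything after operates on loci.
2. **Trimming optimisation** — per-locus gap-threshold sweep; loci whose
   best admissible trim loses more than the data-loss budget (default 30%)
   or retains no informative sites are discarded.
3. **Alignment summaries** — length, P_PIC, missing data per retained locus.
4. **Tree QC** — diameter-outlier leaves flagged and pruned from each gene
   tree (flagged taxa are masked to gaps in the trimmed alignment, since
   realignment is outside this toolkit's scope), then low-support branch
   contraction.
5. **Clock filtering** — root-to-tip variance, tree length, taxon count and
   species-tree concordance per locus; loci failing any criterion are
   excluded from the dating-ready set.
6. **Concordance report** — per species-tree node, gene trees supporting /
   conflicting / uninformative.

A locus discarded at any stage is excluded downstream. All stage tables
are written as TSV as they complete; a JSON manifest records the config,
and per-stage in/out counts. Identical inputs and config produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import pandas as pd

from .alignment_metrics import alignment_summary, summarize_set
from .core_io import (
    Alignment,
    RecoveryMatrix,
    clone_tree,
    read_alignment,
    read_recovery_table,
    read_tree,
    write_alignment,
    write_tree,
)
from .gap_trim_optimizer import TrimConfig, optimize_trim
from .recovery_scoring import coverage_scores, filter_by_score
from .tree_qc import (
    ClockCriteria,
    TreeQCConfig,
    clock_stats,
    collapse_low_support,
    concordance_pies,
    flag_outlier_leaves,
    select_clock_loci,
)

logger = logging.getLogger("hybqc")

__all__ = ["PipelineConfig", "QCReport", "run_qc", "load_inputs"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one QC run.

    ``alignment_dir`` holds one FASTA per locus, ``gene_tree_dir`` one
    newick per locus (matched by file stem); thresholds default to the
    standard cut-offs (coverage 0.5, data loss 30%, diameter 20%,
    support <= 10, concordance > 0.1, rtt variance < 0.024, tree length
    > 0.1, >= 25 taxa).
    """

    alignment_dir: str | Path = ""
    gene_tree_dir: str | Path = ""
    species_tree: str | Path = ""
    recovery_table: str | Path = ""
    out_dir: str | Path = "qc_out"
    score_cutoff: float = 0.5
    trim: TrimConfig = field(default_factory=TrimConfig)
    tree_qc: TreeQCConfig = field(default_factory=TreeQCConfig)
    clock: ClockCriteria = field(default_factory=ClockCriteria)
    keep_going: bool = False


@dataclass
class QCReport:
    scores: pd.DataFrame
    trim_results: pd.DataFrame
    alignment_stats: pd.DataFrame
    flagged_leaves: pd.DataFrame
    clock_table: pd.DataFrame
    concordance: pd.DataFrame
    retained_loci: list[str]
    stage_counts: dict[str, dict[str, int]]


def load_inputs(cfg: PipelineConfig) -> tuple[
    dict[str, Alignment], dict[str, dendropy.Tree], dendropy.Tree,
    RecoveryMatrix
]:
    """Read and reconcile all inputs; loci must appear as both an
    alignment and a gene tree (mismatches are warned about and dropped)."""
    aln_dir = Path(cfg.alignment_dir)
    tree_dir = Path(cfg.gene_tree_dir)
    aln_paths = {p.stem: p for p in sorted(aln_dir.glob("*.fasta"))}
    tree_paths = {p.stem: p for p in sorted(tree_dir.glob("*.nwk"))}
    if not aln_paths or not tree_paths:
        raise ValueError(
            f"no inputs found under {aln_dir} / {tree_dir}"
        )
    shared = sorted(aln_paths.keys() & tree_paths.keys())
    for missing in sorted(aln_paths.keys() ^ tree_paths.keys()):
        logger.warning(
            "locus %s present on only one side (alignment/tree); excluded",
            missing,
        )
    alignments = {l: read_alignment(aln_paths[l]) for l in shared}
    gene_trees = {l: read_tree(tree_paths[l]) for l in shared}
    species = read_tree(cfg.species_tree)
    recovery = read_recovery_table(cfg.recovery_table)
    return alignments, gene_trees, species, recovery


def _mask_taxa(aln: Alignment, taxa: set[str]) -> Alignment:
    """Drop rows for *taxa* (pruned outliers) from the alignment."""
    return aln.select_taxa([t for t in aln.taxa if t not in taxa])


def run_qc(cfg: PipelineConfig) -> QCReport:
    """Execute all stages; returns the report and writes TSVs to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alignments, gene_trees, species, recovery = load_inputs(cfg)
    counts: dict[str, dict[str, int]] = {}

    # --- stage 1: accession coverage filter -------------------------------
    scores = coverage_scores(recovery, axis="accessions")
    retained_acc = set(filter_by_score(scores, cfg.score_cutoff))
    scores_df = pd.DataFrame(
        [
            {
                "accession": s.entity_id,
                "representativeness": s.representativeness,
                "completeness": s.completeness,
                "evenness": s.evenness,
                "score": s.score,
                "retained": s.entity_id in retained_acc,
            }
            for s in scores
        ]
    )
    counts["coverage_filter"] = {
        "in": len(scores), "out": len(retained_acc)
    }
    dropped_acc = {s.entity_id for s in scores} - retained_acc

    work_aln: dict[str, Alignment] = {}
    work_trees: dict[str, dendropy.Tree] = {}
    for l in sorted(alignments):
        aln = _mask_taxa(alignments[l], dropped_acc)
        tree = clone_tree(gene_trees[l])
        drop = [t.taxon.label for t in tree.leaf_node_iter()
                if t.taxon.label in dropped_acc]
        if drop:
            tree.prune_taxa_with_labels(drop)
        if aln.n_taxa < 4 or len(tree.leaf_nodes()) < 4:
            logger.warning("locus %s below 4 taxa after accession filter; "
                           "excluded", l)
            continue
        work_aln[l] = aln
        work_trees[l] = tree

    # --- stage 2: trimming optimisation -----------------------------------
    trim_rows = []
    trimmed: dict[str, Alignment] = {}
    for l in sorted(work_aln):
        res = optimize_trim(work_aln[l], cfg.trim)
        p_before = alignment_summary(work_aln[l]).p_pic
        p_after = (alignment_summary(res.trimmed).p_pic
                   if res.trimmed.length else 0.0)
        trim_rows.append(
            {
                "locus": l,
                "chosen_gt": res.chosen_gt,
                "p_pic_before": round(p_before, 6),
                "p_pic_after": round(p_after, 6),
                "data_loss": round(res.data_loss, 6),
                "verdict": res.verdict,
            }
        )
        if res.verdict == "keep":
            trimmed[l] = res.trimmed
    trim_df = pd.DataFrame(trim_rows)
    counts["trim_filter"] = {"in": len(work_aln), "out": len(trimmed)}

    # --- stage 3: alignment summaries -------------------------------------
    stats = [alignment_summary(trimmed[l]) for l in sorted(trimmed)]
    stats_df = pd.DataFrame([s.as_dict() for s in stats])

    # --- stage 4: tree QC ---------------------------------------------------
    flagged_rows = []
    qc_trees: dict[str, dendropy.Tree] = {}
    for l in sorted(trimmed):
        try:
            flagged, pruned = flag_outlier_leaves(work_trees[l], cfg.tree_qc)
        except ValueError as exc:
            if cfg.keep_going:
                logger.warning("locus %s: %s; skipped", l, exc)
                continue
            raise
        for t in flagged:
            flagged_rows.append({"locus": l, "leaf": t})
        if flagged:
            trimmed[l] = _mask_taxa(trimmed[l], set(flagged))
        qc_trees[l] = collapse_low_support(pruned, cfg.tree_qc)
    flagged_df = pd.DataFrame(flagged_rows, columns=["locus", "leaf"])
    counts["tree_qc"] = {"in": len(trimmed), "out": len(qc_trees)}

    # --- stage 5: clock filtering ------------------------------------------
    clock_rows = []
    lstats = []
    for l in sorted(qc_trees):
        s = clock_stats(qc_trees[l], species, cfg.tree_qc, locus_id=l)
        lstats.append(s)
    retained_loci, failures = select_clock_loci(lstats, cfg.clock)
    for s in lstats:
        clock_rows.append(
            {
                "locus": s.locus_id,
                "rtt_variance": round(s.rtt_variance, 8),
                "tree_length": round(s.tree_length, 6),
                "n_taxa": s.n_taxa,
                "concordance": round(s.concordance, 6),
                "retained": s.locus_id in set(retained_loci),
                "failed": ";".join(failures.get(s.locus_id, [])),
            }
        )
    clock_df = pd.DataFrame(clock_rows)
    counts["clock_filter"] = {"in": len(lstats), "out": len(retained_loci)}

    # --- stage 6: concordance pies -----------------------------------------
    pies = concordance_pies(
        [qc_trees[l] for l in sorted(qc_trees)], species
    )
    pies_df = pd.DataFrame(
        [
            {
                "node": p.node_id,
                "concordant": p.n_concord,
                "conflicting": p.n_conflict,
                "uninformative": p.n_uninformative,
            }
            for p in pies
        ]
    )

    # --- outputs ------------------------------------------------------------
    scores_df.to_csv(out / "coverage_scores.tsv", sep="\t", index=False)
    trim_df.to_csv(out / "trim_report.tsv", sep="\t", index=False)
    stats_df.to_csv(out / "alignment_stats.tsv", sep="\t", index=False)
    flagged_df.to_csv(out / "flagged_leaves.tsv", sep="\t", index=False)
    clock_df.to_csv(out / "clock_filter.tsv", sep="\t", index=False)
    pies_df.to_csv(out / "concordance.tsv", sep="\t", index=False)
    if stats:
        summarize_set(stats).to_csv(
            out / "alignment_summary.tsv", sep="\t", index=False
        )
    (out / "trimmed").mkdir(exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    for l in sorted(qc_trees):
        if l in trimmed:
            write_alignment(trimmed[l], out / "trimmed" / f"{l}.fasta")
        write_tree(qc_trees[l], out / "trees" / f"{l}.nwk")

    manifest = {
        "config": {
            "score_cutoff": cfg.score_cutoff,
            "max_data_loss": cfg.trim.max_data_loss,
            "thresholds": list(cfg.trim.thresholds),
            "diameter_bound": cfg.tree_qc.diameter_bound,
            "support_cutoff": cfg.tree_qc.support_cutoff,
            "clock": asdict(cfg.clock),
        },
        "stage_counts": counts,
        "retained_loci": retained_loci,
        "retained_accessions": sorted(retained_acc),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return QCReport(
        scores=scores_df,
        trim_results=trim_df,
        alignment_stats=stats_df,
        flagged_leaves=flagged_df,
        clock_table=clock_df,
        concordance=pies_df,
        retained_loci=retained_loci,
        stage_counts=counts,
    )
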