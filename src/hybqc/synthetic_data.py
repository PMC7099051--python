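"""Synthetic Hyb-Seq datasets with planted ground truth.

The generator emulates the statistical structure of a target-capture
(Angiosperms-353-style) herbariomics dataset so every QC stage can be
exercised without downloads:

* a pure-birth species tree, scaled to a chosen root-to-tip depth;
* per-locus gene trees that share the species topology with small
  multiplicative branch-length jitter; planted clock violators
  additionally receive stem-lineage rate bursts on two disjoint nested
  clades (lineage-specific accelerations, the form of clock violation
  that neither leaf-outlier pruning nor rerooting can absorb);
* rogue taxa whose terminal branch is rebuilt as a large multiple of the
  tree's mean branch length on every gene tree — contaminant- or
  paralog-like samples whose divergence is unrelated to their placement;
* sequences evolved under the Jukes–Cantor model along each gene tree
  (branch lengths scaled down so columns show realistic conservation);
* age-dependent fragmentary recovery: herbarium accessions lose an
  expected fraction of each target that grows linearly with specimen age,
  with strong Beta-distributed accession-level noise (the weak-correlation,
  huge-variance regime reported for historical collections); DNA-bank and
  silica accessions recover nearly everything;
* fragmentation realised in the alignments as contiguous recovered
  windows, plus a configurable fraction of gap-rich columns (flanking-
  region-like); taxa with zero recovery are absent from the alignment and
  the gene tree.

Every random draw flows from the single integer seed in :class:`SimSpec`;
the same spec always yields byte-identical datasets.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .core_io import (
    Alignment,
    RecoveryMatrix,
    clone_tree,
    set_support,
    write_alignment,
    write_tree,
)

import pandas as pd

__all__ = ["SimSpec", "AgeDecay", "SimDataset", "simulate_dataset",
           "fixture_suite"]

_NUC = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class AgeDecay:
    """Expected recovered fraction as a linear function of collection year."""

    reference_year: int = 2020
    base_fraction: float = 0.9
    slope_per_year: float = 0.004
    floor: float = 0.05

    def __call__(self, year: float) -> float:
        f = self.base_fraction - self.slope_per_year * (self.reference_year - year)
        return float(np.clip(f, self.floor, 1.0))


@dataclass
class SimSpec:
    """Parameters of one synthetic dataset."""

    n_taxa: int = 40
    n_loci: int = 150
    locus_length_mean: float = 613.0
    locus_length_sd: float = 368.0
    locus_length_min: int = 120
    #: expected root-to-tip depth of the species tree, substitutions/site
    subst_rate: float = 0.4
    frag_by_age: AgeDecay = field(default_factory=AgeDecay)
    gap_col_frac: float = 0.10
    rogue_taxa: int = 1
    rogue_multiplier: float = 10.0
    clock_violation_loci: int = 30
    #: planted extra root-to-tip depth (substitutions/site) for the tips of
    #: the rate-shifted clade of each violator locus (uniform draw); clock
    #: violations in real data are lineage-specific rate accelerations, so
    #: one clade's rates are inflated until its tips overshoot by this much
    clock_contrast_range: tuple[float, float] = (1.0, 2.0)
    #: lognormal sigma of per-branch jitter applied to every locus
    clock_jitter_sigma: float = 0.08
    #: branch-length multiplier applied only when evolving sequences, so
    #: alignments show realistic conservation (10-20% informative columns)
    #: while tree statistics keep the depth the clock filter needs
    seq_rate_scale: float = 0.05
    herbarium_frac: float = 0.7
    year_range: tuple[int, int] = (1900, 2015)
    #: Beta concentration of accession-level recovery quality (small =
    #: the noisy, weak-age-correlation regime of historical collections)
    accession_noise: float = 2.0
    locus_noise: float = 10.0
    presence_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.rogue_multiplier <= 1:
            raise ValueError("rogue multiplier must exceed 1")
        if not 0 <= self.gap_col_frac <= 1:
            raise ValueError("gap_col_frac must lie in [0, 1]")


@dataclass
class SimDataset:
    spec: SimSpec
    alignments: dict[str, Alignment]
    gene_trees: dict[str, dendropy.Tree]
    species_tree: dendropy.Tree
    recovery: RecoveryMatrix
    truth: dict


def _species_tree(spec: SimSpec, rng: random.Random) -> dendropy.Tree:
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=spec.n_taxa, rng=rng
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:03d}"
    # scale to the requested root-to-tip depth; floor tiny edges
    tree.seed_node.edge.length = 0.0
    depth = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    factor = spec.subst_rate / depth if depth > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length * factor, 1e-4)
    tree.seed_node.edge.length = 0.0
    return tree


def _beta(rng: np.random.Generator, mean: float, conc: float) -> float:
    mean = float(np.clip(mean, 1e-6, 1.0))
    if mean >= 0.999:
        return 1.0
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def _evolve(tree: dendropy.Tree, length: int,
            rng: np.random.Generator,
            rate_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Jukes–Cantor evolution along *tree*; returns label -> code array."""
    seqs: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            seq = rng.integers(0, 4, size=length, dtype=np.int8)
        else:
            parent = seqs[id(nd.parent_node)]
            b = (nd.edge.length or 0.0) * rate_scale
            p = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            mask = rng.random(length) < p
            seq = parent.copy()
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask]
                             + rng.integers(1, 4, size=n_mut, dtype=np.int8)) % 4
        seqs[id(nd)] = seq
        if nd.is_leaf():
            out[nd.taxon.label] = seq
    return out


def _informative_columns(rows: list[str]) -> str:
    """'0'/'1' string marking parsimony-informative columns (direct count)."""
    if not rows:
        return ""
    flags = []
    for j in range(len(rows[0])):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        flags.append("1" if sum(1 for v in counts.values() if v >= 2) >= 2
                     else "0")
    return "".join(flags)


def simulate_dataset(spec: SimSpec, with_sequences: bool = True) -> SimDataset:
    """Generate a full dataset (trees, recovery, alignments, truth).

    ``with_sequences=False`` skips sequence evolution and alignment
    construction (tree-level studies only need the trees and recovery).
    """
    rng = np.random.default_rng(spec.seed)
    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    species = _species_tree(spec, py_rng)
    taxa = sorted(lf.taxon.label for lf in species.leaf_node_iter())

    # --- rogue taxa: contaminant/paralog-like samples whose divergence is
    # unrelated to their true placement (terminal branch rebuilt below)
    n_rogue = min(spec.rogue_taxa, spec.n_taxa)
    rogues = sorted(
        rng.choice(taxa, size=n_rogue, replace=False).tolist()
    ) if n_rogue else []

    # --- locus structure
    loci = [f"locus{i + 1:03d}" for i in range(spec.n_loci)]
    lengths = {
        l: int(max(spec.locus_length_min,
                   rng.normal(spec.locus_length_mean, spec.locus_length_sd)))
        for l in loci
    }
    violators = sorted(
        rng.choice(loci, size=min(spec.clock_violation_loci, spec.n_loci),
                   replace=False).tolist()
    )
    violator_set = set(violators)
    violation_clades: dict[str, dict] = {}

    # --- accession metadata and recovery quality
    n_herb = int(round(spec.herbarium_frac * spec.n_taxa))
    herb = set(taxa[:n_herb])
    meta_rows = []
    quality: dict[str, float] = {}
    expected_frac: dict[str, float] = {}
    for a in taxa:
        if a in herb:
            year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
            source = "herbarium"
            mu = spec.frag_by_age(year)
            q = _beta(rng, mu, spec.accession_noise)
        else:
            year = int(rng.integers(1995, 2021))
            source = "dna_bank" if rng.random() < 0.5 else "silica"
            mu = 0.95
            q = _beta(rng, mu, 50.0)
        reads_total = int(np.exp(rng.normal(np.log(7.4e5), 0.5)))
        on_target = int(reads_total * _beta(rng, 0.115, 60.0))
        meta_rows.append(
            {"accession": a, "collection_year": year, "source": source,
             "reads_total": reads_total, "reads_on_target": on_target}
        )
        quality[a] = q
        expected_frac[a] = mu

    # --- per-cell recovered fractions and lengths
    rec = pd.DataFrame(0.0, index=taxa, columns=loci)
    frac = {}
    for a in taxa:
        for l in loci:
            f = _beta(rng, quality[a], spec.locus_noise)
            if f < spec.presence_floor:
                f = 0.0
            frac[(a, l)] = f
            rec.loc[a, l] = float(int(round(f * lengths[l])))
    targets = pd.Series({l: float(lengths[l]) for l in loci})
    meta = pd.DataFrame(meta_rows).set_index("accession")
    recovery = RecoveryMatrix(rec, targets, meta)

    # --- gene trees
    gene_trees: dict[str, dendropy.Tree] = {}
    for l in loci:
        gt = clone_tree(species)
        sigma = spec.clock_jitter_sigma
        for edge in gt.preorder_edge_iter():
            if edge.head_node.parent_node is None:
                continue
            m = float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0))
            edge.length = (edge.length or 0.0) * m
        if l in violator_set:
            # lineage-specific rate shift on one sizeable nested clade: a
            # whole lineage accelerates, which a per-leaf outlier test
            # cannot and should not remove. The clade must be nested (not a
            # child of the root) with enough taxa outside it on its own
            # root side, otherwise rerooting absorbs the depth contrast.
            n = spec.n_taxa
            side_of: dict[int, int] = {}
            for k, child in enumerate(gt.seed_node.child_nodes()):
                for nd in child.preorder_iter():
                    side_of[id(nd)] = k
            side_size = {
                k: len(child.leaf_nodes())
                for k, child in enumerate(gt.seed_node.child_nodes())
            }
            floor = max(3, n // 5)

            def _nested(nd) -> bool:
                k = len(nd.leaf_nodes())
                if not max(3, n // 6) <= k <= n // 3:
                    return False
                if nd.parent_node is gt.seed_node:
                    return False
                return side_size[side_of[id(nd)]] - k >= floor

            nodes = [
                nd for nd in gt.preorder_internal_node_iter(
                    exclude_seed_node=True)
                if _nested(nd)
            ] or [
                nd for nd in gt.preorder_internal_node_iter(
                    exclude_seed_node=True)
                if 3 <= len(nd.leaf_nodes()) <= n - 3
            ]
            if nodes:
                # rate bursts along two disjoint stem lineages: every tip
                # of each clade gains the same extra depth, so no single
                # leaf is an outlier and no single rerooting can absorb
                # both contrasts — only the clock statistic catches it
                first = nodes[int(rng.integers(0, len(nodes)))]
                first_leaves = set(x.taxon.label for x in first.leaf_iter())
                others = [
                    nd for nd in nodes
                    if not (set(x.taxon.label for x in nd.leaf_iter())
                            & first_leaves)
                ]
                picks = [first]
                if others:
                    picks.append(others[int(rng.integers(0, len(others)))])
                lo, hi = spec.clock_contrast_range
                entry = []
                for node in picks:
                    contrast = float(rng.uniform(lo, hi))
                    node.edge.length += contrast
                    entry.append({
                        "clade": sorted(
                            x.taxon.label for x in node.leaf_iter()),
                        "contrast": contrast,
                    })
                violation_clades[l] = entry
        if rogues:
            # contaminant-like excess divergence: the rogue's terminal
            # branch is set to multiplier x the tree's mean branch length,
            # independent of its (possibly tiny) true pendant edge
            edges = [e.length for e in gt.preorder_edge_iter()
                     if e.length and e.head_node.parent_node is not None]
            mean_branch = float(np.mean(edges)) if edges else 0.0
            for lf in gt.leaf_node_iter():
                if lf.taxon.label in rogues:
                    lf.edge.length = max(
                        lf.edge.length, spec.rogue_multiplier * mean_branch
                    )
        for nd in gt.preorder_internal_node_iter(exclude_seed_node=True):
            if rng.random() < 0.15:
                set_support(nd, int(rng.integers(0, 21)))
            else:
                set_support(nd, int(rng.integers(60, 101)))
        absent = [a for a in taxa if rec.loc[a, l] == 0]
        if absent:
            gt.prune_taxa_with_labels(absent)
        gene_trees[l] = gt

    # --- alignments
    alignments: dict[str, Alignment] = {}
    informative: dict[str, str] = {}
    if with_sequences:
        for l in loci:
            L = lengths[l]
            codes = _evolve(gene_trees[l], L, rng,
                            rate_scale=spec.seq_rate_scale)
            keep_taxa = [a for a in taxa if a in codes]
            rows = []
            for a in keep_taxa:
                row = _NUC[codes[a]].copy()
                w = int(rec.loc[a, l])
                if w < L:
                    start = int(rng.integers(0, L - w + 1))
                    row[:start] = b"-"
                    row[start + w:] = b"-"
                rows.append(row)
            if rows and spec.gap_col_frac > 0:
                n_gapcols = int(round(spec.gap_col_frac * L))
                cols = rng.choice(L, size=n_gapcols, replace=False)
                for j in cols:
                    hit = rng.random(len(rows)) < rng.uniform(0.5, 0.8)
                    for i in np.nonzero(hit)[0]:
                        rows[i][j] = b"-"
            str_rows = [r.tobytes().decode("ascii") for r in rows]
            alignments[l] = Alignment(l, keep_taxa, str_rows)
            informative[l] = _informative_columns(str_rows)

    # --- independent arithmetic for expected accession retention
    retained = []
    for a in taxa:
        vals = [rec.loc[a, l] for l in loci]
        nz = [v for v in vals if v > 0]
        m = len(loci)
        r = len(nz) / m
        if not nz:
            continue
        c = sum(min(v / targets[l], 1.0)
                for l, v in zip(loci, vals) if v > 0) / len(nz)
        if m == 1:
            e = 1.0
        elif len(nz) <= 1:
            e = 0.0
        else:
            fz = [min(v / targets[l], 1.0)
                  for l, v in zip(loci, vals) if v > 0]
            tot = sum(fz)
            e = -sum((f / tot) * np.log(f / tot) for f in fz) / np.log(m)
        if r * c * e >= 0.5:
            retained.append(a)

    truth = {
        "n_taxa": spec.n_taxa,
        "n_loci": spec.n_loci,
        "taxa": taxa,
        "loci": loci,
        "rogue_taxa": rogues,
        "clock_violation_loci": violators,
        "violation_clades": violation_clades,
        "clock_like_loci": sorted(set(loci) - violator_set),
        "quality": quality,
        "expected_fraction": expected_frac,
        "low_coverage_accessions": sorted(
            a for a in taxa if quality[a] < 0.3
        ),
        "herbarium_accessions": sorted(herb),
        "age_slope_per_year": spec.frag_by_age.slope_per_year,
        "expected_retained_accessions": retained,
        "informative_columns": informative,
    }
    return SimDataset(spec, alignments, gene_trees, species, recovery, truth)


SIZES = {"small": (8, 12), "medium": (40, 150)}


def fixture_suite(
    size: str, out_dir: str | Path, seed: int = 0, **overrides
) -> dict:
    """Write a complete on-disk fixture bundle; returns a path manifest.

    ``small`` is 8 taxa x 12 loci; ``medium`` is 40 taxa x 150 loci
    (echoing a realistic study: a few dozen accessions, a few hundred
    retained regions).
    """
    if size not in SIZES:
        raise ValueError(f"unknown fixture size: {size!r}")
    n_taxa, n_loci = SIZES[size]
    overrides.setdefault("clock_violation_loci", max(1, n_loci // 5))
    spec = SimSpec(n_taxa=n_taxa, n_loci=n_loci, seed=seed, **overrides)
    ds = simulate_dataset(spec)
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "gene_trees").mkdir(parents=True, exist_ok=True)
    aln_paths, tree_paths = {}, {}
    for l, aln in ds.alignments.items():
        p = out / "alignments" / f"{l}.fasta"
        write_alignment(aln, p)
        aln_paths[l] = str(p)
    for l, gt in ds.gene_trees.items():
        p = out / "gene_trees" / f"{l}.nwk"
        write_tree(gt, p)
        tree_paths[l] = str(p)
    sp_path = out / "species_tree.nwk"
    write_tree(ds.species_tree, sp_path)

    rec_path = out / "recovery.tsv"
    rows = []
    for a in ds.recovery.accessions:
        for l in ds.recovery.loci:
            rows.append({
                "accession": a, "locus": l,
                "recovered_length": int(ds.recovery.recovered.loc[a, l]),
                "target_length": int(ds.recovery.target_length[l]),
            })
    df = pd.DataFrame(rows)
    meta = ds.recovery.meta.reset_index().rename(columns={"index": "accession"})
    df = df.merge(meta, on="accession", how="left")
    df.to_csv(rec_path, sep="\t", index=False)

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(ds.truth, indent=1, sort_keys=True))
    manifest = {
        "size": size,
        "seed": seed,
        "alignments": aln_paths,
        "gene_trees": tree_paths,
        "species_tree": str(sp_path),
        "recovery": str(rec_path),
        "truth": str(truth_path),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                 sort_keys=True))
    return manifest
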