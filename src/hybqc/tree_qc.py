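"""Gene-tree QC and locus selection for downstream dating.

Four filters operate on per-locus gene trees against one species tree:

* **Outlier leaves** — a leaf whose removal shrinks the tree diameter (the
  maximum leaf-to-leaf path length) by more than a bound (default 20%)
  betrays an inflated branch (contamination, paralogy, alignment error).
  Flagging is greedy: repeatedly remove the worst offender until none
  exceeds the bound.
* **Low-support contraction** — internal edges with bootstrap support at or
  below a cutoff (default 10, the ``i & b <= 10`` rule) are collapsed into
  polytomies; edges with unknown support are retained.
* **Clock statistics** — root-to-tip variance (near zero under a strict
  molecular clock), total tree length, taxon count, and the fraction of
  species-tree bipartitions (after pruning to the gene tree's taxa) found
  in the gene tree.
* **Clock-locus selection** — loci pass when concordance > 0.1, root-to-tip
  variance < 0.024 (squared substitutions/site), tree length > 0.1 and
  taxon count >= 25; inequalities strict as stated except the taxon floor.

The concordance accounting mirrors bipartition-based gene-tree conflict
summaries: per species-tree node, each gene tree either supports the
bipartition, conflicts with it, or (after restriction to the taxa it
samples) carries no information.

Rooting for root-to-tip statistics is midpoint by default; outgroup
rooting is available. Root-to-tip variance uses the sample (n-1)
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core_io import clone_tree, get_support

__all__ = [
    "TreeQCConfig",
    "ClockCriteria",
    "LocusTreeStats",
    "ConcordanceSummary",
    "leaf_distance_matrix",
    "tree_diameter",
    "flag_outlier_leaves",
    "collapse_low_support",
    "clock_stats",
    "select_clock_loci",
    "concordance_pies",
]


@dataclass
class TreeQCConfig:
    diameter_bound: float = 0.20
    support_cutoff: int = 10
    #: "midpoint" (default), "outgroup", or "keep" (tree already rooted)
    rooting: str = "midpoint"
    outgroup: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.diameter_bound <= 0:
            raise ValueError("diameter_bound must be > 0")
        if not 0 <= self.support_cutoff <= 100:
            raise ValueError("support_cutoff must lie in [0, 100]")
        if self.rooting not in ("midpoint", "outgroup", "keep"):
            raise ValueError(f"unknown rooting: {self.rooting!r}")


@dataclass
class ClockCriteria:
    """Thresholds for clock-locus selection (strict unless noted)."""

    min_concordance: float = 0.1   # concordance must exceed this
    max_rtt_variance: float = 0.024  # variance must be strictly below
    min_tree_length: float = 0.1   # length must exceed this
    min_taxa: int = 25             # inclusive floor


@dataclass
class LocusTreeStats:
    locus_id: str
    rtt_variance: float
    tree_length: float
    n_taxa: int
    concordance: float


@dataclass
class ConcordanceSummary:
    node_id: str
    n_concord: int
    n_conflict: int
    n_uninformative: int


# ---------------------------------------------------------------------------
# Distances and diameter
# ---------------------------------------------------------------------------

def leaf_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf labels and the matrix of pairwise path lengths.

    Raises if any edge on a leaf-to-leaf path lacks a branch length.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))
    missing: list[str] = []

    # per node: (leaf indices below, distances from those leaves to the node)
    store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            store[id(nd)] = (np.array([index[id(nd)]]), np.zeros(1))
            continue
        parts = []
        for ch in nd.child_nodes():
            length = ch.edge.length
            if length is None:
                missing.append(
                    ch.taxon.label if ch.is_leaf() and ch.taxon
                    else (ch.label or "<internal>")
                )
                length = 0.0
            idxs, dists = store.pop(id(ch))
            parts.append((idxs, dists + length))
        for a in range(len(parts)):
            for b in range(a + 1, len(parts)):
                ia, da = parts[a]
                ib, db = parts[b]
                cross = da[:, None] + db[None, :]
                d[np.ix_(ia, ib)] = cross
                d[np.ix_(ib, ia)] = cross.T
        store[id(nd)] = (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
    if missing:
        raise ValueError(
            f"edges above {sorted(set(missing))} lack branch lengths"
        )
    return labels, d


def tree_diameter(tree: dendropy.Tree) -> float:
    """Maximum leaf-to-leaf path length; 0 for a single-leaf tree."""
    labels, d = leaf_distance_matrix(tree)
    if len(labels) < 2:
        return 0.0
    return float(d.max())


def _max_excluding(d: np.ndarray, skip: set[int]) -> float:
    keep = [i for i in range(d.shape[0]) if i not in skip]
    if len(keep) < 2:
        return 0.0
    sub = d[np.ix_(keep, keep)]
    return float(sub.max())


def flag_outlier_leaves(
    tree: dendropy.Tree, cfg: TreeQCConfig | None = None
) -> tuple[list[str], dendropy.Tree]:
    """Greedily flag leaves whose removal shrinks the diameter by > bound.

    At each step the leaf maximising ``(D - D_minus) / D_minus`` is flagged
    if that relative excess exceeds ``cfg.diameter_bound``; the loop repeats
    on the reduced leaf set. Returns the flagged labels (in removal order)
    and the pruned tree. Stops with a warning rather than pruning below
    three leaves.
    """
    cfg = cfg or TreeQCConfig()
    labels, d = leaf_distance_matrix(tree)
    if len(labels) < 4:
        raise ValueError("outlier flagging needs >= 4 leaves")
    removed: set[int] = set()
    flagged: list[str] = []
    while True:
        active = [i for i in range(len(labels)) if i not in removed]
        if len(active) < 3:
            break
        diam = _max_excluding(d, removed)
        if diam == 0:
            break
        best_i, best_ratio = -1, -np.inf
        for i in active:
            d_minus = _max_excluding(d, removed | {i})
            ratio = np.inf if d_minus == 0 else (diam - d_minus) / d_minus
            if ratio > best_ratio:
                best_i, best_ratio = i, ratio
        if best_ratio <= cfg.diameter_bound:
            break
        if len(active) - 1 < 3:
            warnings.warn(
                "outlier pruning would leave fewer than 3 leaves; stopping"
            )
            break
        removed.add(best_i)
        flagged.append(labels[best_i])
    pruned = clone_tree(tree)
    if flagged:
        pruned.prune_taxa_with_labels(flagged)
    return flagged, pruned


# ---------------------------------------------------------------------------
# Support contraction
# ---------------------------------------------------------------------------

def collapse_low_support(
    tree: dendropy.Tree, cfg: TreeQCConfig | None = None
) -> dendropy.Tree:
    """Contract internal edges with support <= cutoff into polytomies.

    The leaf set is untouched; edges with unknown support are retained.
    Idempotent.
    """
    cfg = cfg or TreeQCConfig()
    out = clone_tree(tree)
    to_collapse = []
    for nd in out.preorder_internal_node_iter(exclude_seed_node=True):
        sup = get_support(nd)
        if sup is not None and sup <= cfg.support_cutoff:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# Bipartitions (label-based, namespace-free)
# ---------------------------------------------------------------------------

def _leafset(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _splits(tree: dendropy.Tree, universe: frozenset[str]) -> set[frozenset]:
    """Nontrivial bipartitions restricted to *universe*.

    Each split is a frozenset of its two sides (frozensets of labels),
    both of size >= 2 after restriction.
    """
    below: dict[int, set[str]] = {}
    splits: set[frozenset] = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            s = {nd.taxon.label} & universe
        else:
            s = set()
            for ch in nd.child_nodes():
                s |= below.pop(id(ch))
            side = frozenset(s)
            other = universe - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(frozenset({side, other}))
        below[id(nd)] = s
    return splits


def _compatible(split_a: frozenset, split_b: frozenset) -> bool:
    """Two splits on the same universe are compatible iff some cross-
    intersection is empty."""
    a1, a2 = tuple(split_a)
    b1, b2 = tuple(split_b)
    return not all((a1 & b1, a1 & b2, a2 & b1, a2 & b2))


# ---------------------------------------------------------------------------
# Clock statistics
# ---------------------------------------------------------------------------

def _root(tree: dendropy.Tree, cfg: TreeQCConfig) -> dendropy.Tree:
    work = clone_tree(tree)
    if cfg.rooting == "keep":
        pass
    elif cfg.rooting == "midpoint":
        work.reroot_at_midpoint(update_bipartitions=False)
    else:
        labels = set(cfg.outgroup) & _leafset(work)
        if not labels:
            raise ValueError("no outgroup taxa present in tree")
        if len(labels) == 1:
            node = work.find_node_with_taxon_label(next(iter(labels)))
        else:
            node = work.mrca(taxon_labels=sorted(labels))
        if node is not work.seed_node:
            work.reroot_at_edge(node.edge, update_bipartitions=False)
    return work


def root_to_tip_lengths(tree: dendropy.Tree) -> np.ndarray:
    depths = []
    for nd in tree.preorder_node_iter():
        parent_depth = getattr(nd.parent_node, "_rtt_depth", 0.0) \
            if nd.parent_node is not None else 0.0
        nd._rtt_depth = parent_depth + (nd.edge.length or 0.0)
        if nd.is_leaf():
            depths.append(nd._rtt_depth)
    return np.asarray(depths)


def concordance_fraction(gene: dendropy.Tree, species: dendropy.Tree) -> float:
    """Fraction of species-tree bipartitions, pruned to the gene tree's
    taxa, that occur in the gene tree; 1.0 when none is testable."""
    shared = _leafset(gene) & _leafset(species)
    if len(shared) < 2:
        raise ValueError("fewer than 2 taxa shared with the species tree")
    sp_splits = _splits(species, frozenset(shared))
    if not sp_splits:
        return 1.0
    gene_splits = _splits(gene, frozenset(shared))
    hit = sum(1 for s in sp_splits if s in gene_splits)
    return hit / len(sp_splits)


def clock_stats(
    gene: dendropy.Tree,
    species: dendropy.Tree,
    cfg: TreeQCConfig | None = None,
    locus_id: str = "",
) -> LocusTreeStats:
    """Root-to-tip variance, tree length, taxon count and concordance."""
    cfg = cfg or TreeQCConfig()
    rooted = _root(gene, cfg)
    depths = root_to_tip_lengths(rooted)
    var = float(np.var(depths, ddof=1)) if len(depths) >= 2 else 0.0
    return LocusTreeStats(
        locus_id=locus_id,
        rtt_variance=var,
        tree_length=float(rooted.length()),
        n_taxa=len(depths),
        concordance=concordance_fraction(gene, species),
    )


def select_clock_loci(
    stats: list[LocusTreeStats], criteria: ClockCriteria | None = None
) -> tuple[list[str], dict[str, list[str]]]:
    """Loci meeting all four criteria, plus per-locus failure reasons."""
    criteria = criteria or ClockCriteria()
    retained: list[str] = []
    failures: dict[str, list[str]] = {}
    for s in stats:
        failed = []
        if not s.concordance > criteria.min_concordance:
            failed.append("concordance")
        if not s.rtt_variance < criteria.max_rtt_variance:
            failed.append("rtt_variance")
        if not s.tree_length > criteria.min_tree_length:
            failed.append("tree_length")
        if not s.n_taxa >= criteria.min_taxa:
            failed.append("n_taxa")
        if failed:
            failures[s.locus_id] = failed
        else:
            retained.append(s.locus_id)
    return retained, failures


# ---------------------------------------------------------------------------
# Concordance pies
# ---------------------------------------------------------------------------

def _split_id(split: frozenset, universe: frozenset[str]) -> str:
    sides = sorted(
        (sorted(side) for side in split), key=lambda s: (len(s), s)
    )
    return ",".join(sides[0])


def concordance_pies(
    genes: list[dendropy.Tree], species: dendropy.Tree
) -> list[ConcordanceSummary]:
    """Per species-tree bipartition: gene trees supporting it, conflicting
    with it, or uninformative after restriction to their sampled taxa."""
    sp_taxa = _leafset(species)
    sp_splits = sorted(
        _splits(species, sp_taxa), key=lambda s: _split_id(s, sp_taxa)
    )
    gene_info = []
    for g in genes:
        taxa = _leafset(g) & sp_taxa
        gene_info.append((taxa, g))

    out = []
    for split in sp_splits:
        x, y = tuple(split)
        n_c = n_x = n_u = 0
        for taxa, g in gene_info:
            xr, yr = x & taxa, y & taxa
            if len(xr) < 2 or len(yr) < 2:
                n_u += 1
                continue
            universe = frozenset(xr | yr)
            restricted = frozenset({frozenset(xr), frozenset(yr)})
            g_splits = _splits(g, universe)
            if restricted in g_splits:
                n_c += 1
            elif any(not _compatible(restricted, gs) for gs in g_splits):
                n_x += 1
            else:
                n_u += 1
        out.append(
            ConcordanceSummary(_split_id(split, sp_taxa), n_c, n_x, n_u)
        )
    return out
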