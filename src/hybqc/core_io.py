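"""Domain types and readers/writers for the formats the QC pipeline touches.

Everything downstream works on three in-memory containers:

* :class:`Alignment` — one per-locus multiple sequence alignment (gapped DNA).
* dendropy :class:`~dendropy.Tree` objects for gene and species trees, with
  integer bootstrap/posterior support carried on internal-node *labels* (the
  dialect written by IQ-TREE, RAxML and friends).
* :class:`RecoveryMatrix` — the accession x locus grid of recovered target
  lengths produced by a capture-assembly tool, plus sample metadata.

Alignment columns are 0-based half-open internally; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("hybqc")

__all__ = [
    "Alignment",
    "RecoveryMatrix",
    "MalformedAlignmentError",
    "DuplicateLabelError",
    "NewickParseError",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "parse_tree",
    "write_tree",
    "tree_to_newick",
    "clone_tree",
    "get_support",
    "set_support",
    "read_recovery_table",
    "write_recovery_table",
    "configure_logging",
]

#: Valid upper-case residue characters: the four states, IUPAC ambiguity
#: codes, N, gap and unknown.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")


class MalformedAlignmentError(ValueError):
    """Rows of unequal length in an alignment."""


class DuplicateLabelError(ValueError):
    """Two records share a taxon label."""


class NewickParseError(ValueError):
    """Newick text is syntactically invalid; carries the character offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


@dataclass
class Alignment:
    """An equal-length gapped DNA alignment for one locus.

    Parameters
    ----------
    locus_id:
        Identifier of the locus.
    taxa:
        Ordered accession identifiers, one per row; must be unique.
    rows:
        One character string per accession, all the same length, over
        ``{A,C,G,T, IUPAC codes, N, -, ?}`` (stored upper case).
    """

    locus_id: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise MalformedAlignmentError(
                f"{self.locus_id}: {len(self.taxa)} taxa but {len(self.rows)} rows"
            )
        seen: set[str] = set()
        for t in self.taxa:
            if t in seen:
                raise DuplicateLabelError(f"duplicate taxon label {t!r}")
            seen.add(t)
        if self.rows:
            n = len(self.rows[0])
            for t, r in zip(self.taxa, self.rows):
                if len(r) != n:
                    raise MalformedAlignmentError(
                        f"{self.locus_id}: row for taxon {t!r} has length "
                        f"{len(r)}, expected {n}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        """Number of columns (bp)."""
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        """Rows as an ``(n_taxa, length)`` array of single-byte strings."""
        if not self.rows:
            return np.empty((0, 0), dtype="S1")
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_taxa, self.length)

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    def select_columns(self, keep: Sequence[int] | np.ndarray) -> "Alignment":
        """New alignment containing only the given (0-based) columns, in order."""
        keep = list(keep)
        rows = ["".join(r[j] for j in keep) for r in self.rows]
        return Alignment(self.locus_id, list(self.taxa), rows)

    def select_taxa(self, taxa: Iterable[str]) -> "Alignment":
        """New alignment restricted to the given taxa (input row order kept)."""
        wanted = set(taxa)
        pairs = [(t, r) for t, r in zip(self.taxa, self.rows) if t in wanted]
        return Alignment(self.locus_id, [t for t, _ in pairs], [r for _, r in pairs])


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a per-locus alignment; sequences are upper-cased, order preserved.

    An empty file yields an alignment with zero taxa and length zero. Ragged
    rows raise :class:`MalformedAlignmentError` naming the offending taxon;
    repeated labels raise :class:`DuplicateLabelError`.
    """
    path = Path(path)
    if format.lower() != "fasta":
        raise ValueError(f"unsupported alignment format: {format!r}")
    taxa: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(locus_id=path.stem, taxa=taxa, rows=rows)


def write_alignment(aln: Alignment, path: str | Path, width: int = 80) -> None:
    """Write an alignment as wrapped FASTA."""
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n")
            for i in range(0, max(len(r), 1), width):
                fh.write(r[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

_COMMENT_SUPPORT_RE = re.compile(r"\)\s*\[&?[^]]*?support=(\d+)[^]]*\]")


def get_support(node: dendropy.Node) -> int | None:
    """Integer support of the edge above *node*, or None when unknown.

    Support lives in the node label (the convention of common ML tools); a
    label that is not an integer in [0, 100] counts as unknown.
    """
    if node.label is None:
        return None
    try:
        v = int(str(node.label))
    except ValueError:
        return None
    return v if 0 <= v <= 100 else None


def set_support(node: dendropy.Node, value: int | None) -> None:
    node.label = None if value is None else str(int(value))


def _check_balanced(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character {i}", offset=i
                )
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' at end of input (character {len(text)})",
            offset=len(text),
        )


def parse_tree(text: str, support_from: str = "label") -> dendropy.Tree:
    """Parse newick text into a dendropy tree.

    Internal-node labels are kept verbatim (interpret via :func:`get_support`).
    Missing branch lengths default to 0. ``support_from="comment"`` accepts
    support embedded in bracket comments (``)[&support=95]``) instead.
    """
    _check_balanced(text)
    if support_from == "comment":
        text = _COMMENT_SUPPORT_RE.sub(lambda m: ")" + m.group(1), text)
        text = re.sub(r"\[[^]]*\]", "", text)
    elif support_from != "label":
        raise ValueError(f"unknown support_from: {support_from!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"newick parse failure: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def read_tree(path: str | Path, support_from: str = "label") -> dendropy.Tree:
    """Read a newick tree file (first tree in the file)."""
    return parse_tree(Path(path).read_text(), support_from=support_from)


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Canonical newick string: labels as-is, branch lengths, no quoting fluff."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_leaf_node_labels=False,
        ).strip()
        + "\n"
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy with its own taxon namespace (labels preserved)."""
    return parse_tree(tree_to_newick(tree))


# ---------------------------------------------------------------------------
# Recovery matrix
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("accession", "locus", "recovered_length", "target_length")
META_COLUMNS = ("collection_year", "source", "reads_total", "reads_on_target")
SOURCES = ("herbarium", "dna_bank", "silica")


@dataclass
class RecoveryMatrix:
    """Accession x locus recovered target lengths plus sample metadata.

    ``recovered`` is a DataFrame (index = accessions, columns = loci) of
    recovered lengths in bp; absent pairs are 0. ``target_length`` maps each
    locus to its reference length. ``meta`` (optional) is indexed by accession
    with columns among ``collection_year``, ``source``, ``reads_total``,
    ``reads_on_target``.
    """

    recovered: pd.DataFrame
    target_length: pd.Series
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.recovered = self.recovered.astype(float)
        self.recovered.index.name = "accession"
        self.recovered.columns.name = "locus"
        self.target_length = self.target_length.astype(float)
        self.target_length.index.name = "locus"
        if (self.recovered.values < 0).any():
            raise ValueError("recovered_length must be >= 0")
        if (self.target_length <= 0).any():
            raise ValueError("target_length must be > 0")
        unknown = set(self.recovered.columns) - set(self.target_length.index)
        if unknown:
            raise ValueError(f"loci without target lengths: {sorted(unknown)}")
        if not self.meta.empty and {"reads_total", "reads_on_target"} <= set(
            self.meta.columns
        ):
            both = self.meta[["reads_total", "reads_on_target"]].dropna()
            if (both["reads_on_target"] > both["reads_total"]).any():
                raise ValueError("reads_on_target exceeds reads_total")

    @property
    def accessions(self) -> list[str]:
        return list(self.recovered.index)

    @property
    def loci(self) -> list[str]:
        return list(self.recovered.columns)

    def transpose(self) -> "RecoveryMatrix":
        """Swap the roles of accessions and loci (target lengths follow loci).

        Used for symmetry checks; the transposed matrix reuses the original
        per-locus target lengths indexed by the new column labels.
        """
        t = self.recovered.T
        targets = pd.Series(
            {a: self.target_length.mean() for a in t.columns}, dtype=float
        )
        return RecoveryMatrix(t, targets)


def read_recovery_table(
    path: str | Path,
    targets: str | Path | None = None,
    meta: str | Path | None = None,
) -> RecoveryMatrix:
    """Read a recovery table in long or wide form.

    Long form: TSV with columns ``accession, locus, recovered_length`` and
    either a ``target_length`` column or a companion *targets* TSV
    (``locus, target_length``). Metadata columns (collection_year, source,
    reads_total, reads_on_target) are picked up when present, or from a
    companion *meta* TSV indexed by accession. Wide form: first column
    ``accession``, remaining columns are loci; requires *targets*.

    Absent (accession, locus) pairs become recovered_length 0.
    """
    df = pd.read_csv(path, sep="\t")
    target_series: pd.Series | None = None
    if targets is not None:
        tdf = pd.read_csv(targets, sep="\t")
        target_series = tdf.set_index("locus")["target_length"].astype(float)

    meta_df = pd.DataFrame()
    if meta is not None:
        meta_df = pd.read_csv(meta, sep="\t").set_index("accession")

    if {"accession", "locus", "recovered_length"} <= set(df.columns):
        if (df["recovered_length"] < 0).any():
            bad = df[df["recovered_length"] < 0].iloc[0]
            raise ValueError(
                f"negative recovered_length for ({bad['accession']}, {bad['locus']})"
            )
        wide = (
            df.pivot_table(
                index="accession",
                columns="locus",
                values="recovered_length",
                aggfunc="sum",
                fill_value=0.0,
            )
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
        if target_series is None:
            if "target_length" not in df.columns:
                raise ValueError(
                    "long-form table needs a target_length column or a targets file"
                )
            target_series = (
                df.groupby("locus")["target_length"].first().astype(float)
            )
        extra = set(wide.columns) - set(target_series.index)
        if extra:
            raise ValueError(f"cells reference unknown loci: {sorted(extra)}")
        if meta_df.empty:
            present = [c for c in META_COLUMNS if c in df.columns]
            if present:
                meta_df = df.groupby("accession")[present].first()
        return RecoveryMatrix(wide, target_series, meta_df)

    # wide form
    if "accession" not in df.columns:
        raise ValueError("cannot recognise recovery table layout")
    wide = df.set_index("accession").sort_index(axis=0).sort_index(axis=1)
    if (wide.values < 0).any():
        raise ValueError("negative recovered_length in wide-form table")
    if target_series is None:
        raise ValueError("wide-form table requires a targets file")
    extra = set(wide.columns) - set(target_series.index)
    if extra:
        raise ValueError(f"cells reference unknown loci: {sorted(extra)}")
    return RecoveryMatrix(wide.astype(float), target_series, meta_df)


def write_recovery_table(
    m: RecoveryMatrix, path: str | Path, form: str = "long"
) -> None:
    """Write a recovery matrix as TSV (long or wide form)."""
    if form == "long":
        rows = []
        for a in m.accessions:
            for l in m.loci:
                rows.append(
                    {
                        "accession": a,
                        "locus": l,
                        "recovered_length": m.recovered.loc[a, l],
                        "target_length": m.target_length[l],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif form == "wide":
        m.recovered.rename_axis("accession").to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown form: {form!r}")


def configure_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr; verbosity 0=WARNING, 1=INFO, 2+=DEBUG."""
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbosity, 2)]
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
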