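"""Readers/writers for the formats the pipeline touches.

Per-locus aligned FASTA, Newick gene trees with node support, a TSV
specimen table, and the cross-referenced multilocus dataset assembled
from them.  Alignment coordinates are 1-based and inclusive throughout
the package.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet


class FormatError(ValueError):
    """A structural problem in an input file (bad record, bad range)."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """An aligned set of sequences for one locus.

    ``states`` is an (n_specimens, columns) array of single uppercase
    characters over the package alphabet.  Columns are addressed 1-based
    and inclusive everywhere in the public API.
    """

    locus_name: str
    specimen_ids: list[str]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.ndim != 2:
            raise FormatError("alignment states must be a 2-D character array")
        if len(self.specimen_ids) != self.states.shape[0]:
            raise FormatError("specimen_ids length does not match state rows")
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            dupes = sorted({s for s in self.specimen_ids
                            if self.specimen_ids.count(s) > 1})
            raise FormatError(f"duplicate specimen ids: {dupes}")
        bad = set(np.unique(self.states)) - alphabet.VALID_CHARS
        if bad:
            raise FormatError(f"invalid states in alignment: {sorted(bad)!r}")
        self._masks: np.ndarray | None = None

    @property
    def n_specimens(self) -> int:
        return self.states.shape[0]

    @property
    def columns(self) -> int:
        return self.states.shape[1]

    @property
    def masks(self) -> np.ndarray:
        """Bit-mask encoding of ``states`` (cached)."""
        if self._masks is None:
            self._masks = alphabet.masks(self.states)
        return self._masks

    def index_of(self, specimen_id: str) -> int:
        try:
            return self.specimen_ids.index(specimen_id)
        except ValueError:
            raise KeyError(f"specimen {specimen_id!r} not in alignment "
                           f"{self.locus_name!r}") from None

    def row(self, specimen_id: str) -> str:
        return "".join(self.states[self.index_of(specimen_id)])

    def subset(self, specimen_ids: Iterable[str]) -> "Alignment":
        ids = [s for s in self.specimen_ids if s in set(specimen_ids)]
        idx = [self.index_of(s) for s in ids]
        return Alignment(self.locus_name, ids, self.states[idx])


def read_alignment(path: str | os.PathLike, locus_name: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Record order is preserved; sequences are uppercased and U is folded
    into T.  Unequal record lengths, duplicate ids and empty files raise
    :class:`FormatError`.
    """
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    ids = [r.id for r in records]
    try:
        rows = [alphabet.normalize(str(r.seq)) for r in records]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    length = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != length:
            raise FormatError(
                f"{path}: record {rid!r} has length {len(row)}, "
                f"expected {length} (alignment must be rectangular)")
    return Alignment(locus_name, ids, alphabet.char_matrix(rows))


def write_alignment(aln: Alignment, path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq("".join(row)), id=sid, description="")
               for sid, row in zip(aln.specimen_ids, aln.states)]
    SeqIO.write(records, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# Specimen table
# ---------------------------------------------------------------------------

SPECIMEN_COLUMNS = ["specimen_id", "clade", "locality", "outgroup", "type_status"]


@dataclass
class SpecimenTable:
    """Specimen metadata: a-priori clade label, locality, outgroup and
    type status (holotype/neotype/none)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPECIMEN_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"specimen table missing columns: {missing}")
        ids = self.table["specimen_id"]
        if ids.duplicated().any():
            raise FormatError(
                f"duplicate specimen ids: {sorted(ids[ids.duplicated()])}")
        self.table = self.table.reset_index(drop=True)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.table["specimen_id"])

    @property
    def outgroup_ids(self) -> list[str]:
        return list(self.table.loc[self.table["outgroup"], "specimen_id"])

    def clade_partition(self) -> dict[str, str]:
        """A-priori partition: specimen -> clade label (ingroup, labelled)."""
        sub = self.table[(~self.table["outgroup"])
                         & (self.table["clade"] != "")]
        return dict(zip(sub["specimen_id"], sub["clade"]))

    def type_specimen(self, clade: str) -> str | None:
        sub = self.table[(self.table["clade"] == clade)
                         & (self.table["type_status"].isin(["holotype",
                                                            "neotype"]))]
        if len(sub):
            return str(sub["specimen_id"].iloc[0])
        return None


def read_specimen_table(path: str | os.PathLike) -> SpecimenTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "outgroup" in df.columns:
        df["outgroup"] = df["outgroup"].str.lower().isin(
            ["1", "true", "yes", "y"])
    return SpecimenTable(df)


def write_specimen_table(table: SpecimenTable, path: str | os.PathLike) -> None:
    out = table.table.copy()
    out["outgroup"] = out["outgroup"].map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

SUPPORT_RANGES = {"bootstrap_percent": (0.0, 100.0),
                  "posterior_probability": (0.0, 1.0)}


@dataclass
class SupportTree:
    """A gene tree with per-internal-node support.

    Internal nodes without a support value are explicitly *unsupported*
    (``node.support_value is None``), never silently zero.
    """

    tree: dendropy.Tree
    support_kind: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.support_kind not in SUPPORT_RANGES:
            raise ValueError(f"unknown support kind {self.support_kind!r}")

    @property
    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def has_branch_lengths(self) -> bool:
        return all(e.length is not None
                   for e in self.tree.preorder_edge_iter()
                   if e.head_node is not self.tree.seed_node)


def _annotate_support(tree: dendropy.Tree, support_kind: str,
                      source: str) -> None:
    lo, hi = SUPPORT_RANGES[support_kind]
    for nd in tree.preorder_node_iter():
        value = None
        if not nd.is_leaf():
            label = nd.label
            if label not in (None, ""):
                try:
                    value = float(label)
                except ValueError:
                    raise FormatError(
                        f"{source}: internal node label {label!r} is not a "
                        f"numeric support value") from None
                if not lo <= value <= hi:
                    raise FormatError(
                        f"{source}: support {value} outside "
                        f"[{lo}, {hi}] for kind {support_kind}")
        nd.support_value = value


def parse_tree(newick: str, support_kind: str, name: str = "") -> SupportTree:
    """Parse a Newick string whose internal-node labels carry support."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise FormatError(f"unparseable Newick: {exc}") from exc
    _annotate_support(tree, support_kind, name or "<string>")
    return SupportTree(tree, support_kind, name)


def read_tree(path: str | os.PathLike, support_kind: str) -> SupportTree:
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty tree file")
    st = parse_tree(text, support_kind, name=os.fspath(path))
    st.name = os.path.basename(os.fspath(path))
    return st


def write_tree(stree: SupportTree, path: str | os.PathLike) -> None:
    for nd in stree.tree.preorder_node_iter():
        if not nd.is_leaf():
            sv = getattr(nd, "support_value", None)
            nd.label = None if sv is None else format(sv, "g")
    stree.tree.write(path=os.fspath(path), schema="newick",
                     unquoted_underscores=True,
                     suppress_rooting=True)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class MultiLocusDataset:
    """Per-locus alignments + specimen table + per-locus gene trees.

    ``trees`` maps locus -> method ("ml"/"bayes"/"true"...) -> SupportTree.
    A specimen may be absent from some loci; ``missing_by_locus`` lists
    the table specimens not sequenced at each locus and ``unannotated``
    the alignment specimens absent from the table.
    """

    loci: dict[str, Alignment]
    specimens: SpecimenTable
    trees: dict[str, dict[str, SupportTree]] = field(default_factory=dict)
    missing_by_locus: dict[str, list[str]] = field(default_factory=dict)
    unannotated: dict[str, list[str]] = field(default_factory=dict)

    def locus_counts(self) -> dict[str, int]:
        return {name: aln.n_specimens for name, aln in self.loci.items()}


def assemble_dataset(alignments: Mapping[str, Alignment],
                     table: SpecimenTable,
                     trees: Mapping[str, Mapping[str, SupportTree]] | None = None,
                     ) -> MultiLocusDataset:
    """Cross-reference alignments, specimen table and trees.

    Tree leaves must all be present in the specimen table; alignment
    specimens absent from the table are reported (``unannotated``), not
    dropped.
    """
    table_ids = set(table.specimen_ids)
    trees = {k: dict(v) for k, v in (trees or {}).items()}
    missing: dict[str, list[str]] = {}
    unannotated: dict[str, list[str]] = {}
    for name, aln in alignments.items():
        aln_ids = set(aln.specimen_ids)
        missing[name] = sorted(table_ids - aln_ids)
        extra = [s for s in aln.specimen_ids if s not in table_ids]
        if extra:
            unannotated[name] = extra
    for locus, by_method in trees.items():
        for method, stree in by_method.items():
            stray = sorted(stree.leaf_labels - table_ids)
            if stray:
                raise FormatError(
                    f"tree {locus}/{method}: leaves not in specimen table: "
                    f"{stray}")
    return MultiLocusDataset(dict(alignments), table, trees,
                             missing, unannotated)
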