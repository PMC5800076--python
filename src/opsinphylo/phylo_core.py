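"""Shared domain types and readers/writers for trees, codon alignments and trait tables.

Trees are rooted and treated as given (no re-rooting); branch values are
non-negative reals whose meaning depends on context: expected substitutions
per site for time-trees, dimensionless dN/dS for omega-trees. The genetic
code is fixed to the universal code with 61 sense codons, ordered
alphabetically over (A, C, G, T) triplets with the three stops removed.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

MISSING = -1

STOP_CODONS = ("TAA", "TAG", "TGA")
NUCLEOTIDES = "ACGT"
#: the 61 sense codons of the universal code, alphabetical over ACGT triplets
CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_UNIVERSAL_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
#: amino acid encoded by each sense codon, in CODONS order
CODON_AMINO_ACIDS = tuple(_UNIVERSAL_CODE[c] for c in CODONS)

ACTIVITY_PATTERNS = ("nocturnal", "cathemeral", "diurnal", "unknown")


class PhyloError(Exception):
    """Base class for errors raised by this package."""


class NewickParseError(PhyloError):
    pass


class ValidationError(PhyloError):
    pass


class TreeNode:
    """A node of a rooted tree.

    ``length`` is the value of the branch subtending the node (0.0 at the
    root).  Tip labels are mandatory and unique; internal labels optional.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=0.0, children=None):
        self.label = label
        self.length = float(length)
        self.children = list(children) if children else []
        self.parent = None
        for child in self.children:
            child.parent = self

    @property
    def is_tip(self):
        return not self.children

    def add_child(self, node):
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, {self.length})"


class Tree:
    """A rooted tree with non-negative branch values.

    Polytomies are allowed; downstream likelihood machinery supports them
    even though codeml itself requires binary trees.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.validate()

    # -- traversal -----------------------------------------------------

    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self):
        return [n for n in self.postorder() if n.is_tip]

    def branches(self):
        """All non-root nodes (each identifies the branch above it)."""
        return [n for n in self.postorder() if n.parent is not None]

    @property
    def tip_labels(self):
        return [t.label for t in self.tips()]

    @property
    def n_tips(self):
        return len(self.tips())

    def find(self, label):
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def branch_ids(self):
        """Stable identifier per branch: tip label, or internal label, or
        a deterministic postorder index ``N<k>``."""
        ids = {}
        k = 0
        for node in self.postorder():
            if node.parent is None:
                continue
            if node.label:
                ids[id(node)] = node.label
            else:
                ids[id(node)] = f"N{k}"
            k += 1
        return ids

    def label_internal(self, prefix="N"):
        """Assign deterministic labels to unlabelled internal nodes (in place)."""
        k = 0
        for node in self.postorder():
            if not node.is_tip and not node.label:
                node.label = f"{prefix}{k}"
            if not node.is_tip:
                k += 1
        return self

    def copy(self):
        def rec(node):
            return TreeNode(node.label, node.length, [rec(c) for c in node.children])

        return Tree(rec(self.root))

    # -- validation & metrics ------------------------------------------

    def validate(self):
        seen = set()
        for node in self.postorder():
            if node.length < 0:
                raise ValidationError(
                    f"negative branch value {node.length} at node {node.label!r}"
                )
            if node.is_tip:
                if not node.label:
                    raise ValidationError("tip with empty label")
                if node.label in seen:
                    raise ValidationError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
        for node in self.postorder():
            for child in node.children:
                if child.parent is not node:
                    raise ValidationError("inconsistent parent pointers")
        return self

    def depths(self):
        """Root-to-node path sums, keyed by node identity."""
        depth = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[id(node)] = depth[id(node.parent)] + node.length
        return depth

    def check_tip_coverage(self, ids):
        """Require the tip set to equal or contain ``ids``; raise listing
        the difference otherwise."""
        tips = set(self.tip_labels)
        missing = set(ids) - tips
        if missing:
            raise ValidationError(
                f"tree lacks tips for record ids: {sorted(missing)}"
            )

    def __eq__(self, other):
        if not isinstance(other, Tree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __repr__(self):  # pragma: no cover
        return f"Tree(n_tips={self.n_tips})"


def parse_newick(text: str) -> Tree:
    """Parse a rooted newick string into a :class:`Tree`.

    Branch lengths are preserved at full precision; a missing length is
    read as 0.0 (common for roots). Malformed input raises
    :class:`NewickParseError` naming the offending position.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        pos = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None:
            pos = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed newick{pos}: {exc}") from exc

    def convert(dnode):
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if length < 0:
            raise ValidationError(
                f"negative branch length {length} on node {label!r}"
            )
        return TreeNode(label, length, [convert(c) for c in dnode.child_nodes()])

    root = convert(dtree.seed_node)
    if root.is_tip:
        raise NewickParseError("newick describes a single node, not a tree")
    return Tree(root)


def _format_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: Tree) -> str:
    """Serialize a tree to newick with full-precision branch lengths."""

    def rec(node):
        if node.is_tip:
            core = node.label
        else:
            core = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                core += node.label
        if node.parent is None:
            return core
        return f"{core}:{_format_length(node.length)}"

    return rec(tree.root) + ";"


def patristic_distances(tree: Tree) -> pd.DataFrame:
    """Tip-by-tip matrix of path-length distances along the tree."""
    tips = tree.tips()
    labels = [t.label for t in tips]
    depth = tree.depths()
    # ancestor chains as dicts node-id -> depth, for LCA lookup
    chains = []
    for tip in tips:
        chain = {}
        node = tip
        while node is not None:
            chain[id(node)] = depth[id(node)]
            node = node.parent
        chains.append(chain)
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            node = tips[j]
            while id(node) not in chains[i]:
                node = node.parent
            lca_depth = depth[id(node)]
            d[i, j] = d[j, i] = (
                depth[id(tips[i])] + depth[id(tips[j])] - 2.0 * lca_depth
            )
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass
class CodonAlignment:
    """Species-by-codon-site matrix over the 61 sense codons.

    ``codons[i, s]`` is the index of the codon in :data:`CODONS`, or
    :data:`MISSING` for triplets containing gaps, ambiguity characters or
    stops.
    """

    sequence_ids: list[str]
    codons: np.ndarray  # (n_sequences, n_sites) int16

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2:
            raise ValidationError("codon matrix must be 2-D")
        if len(self.sequence_ids) != self.codons.shape[0]:
            raise ValidationError("sequence id count does not match matrix rows")
        if self.n_codon_sites < 1:
            raise ValidationError("alignment must contain at least one codon site")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValidationError("duplicate sequence ids")
        bad = (self.codons < MISSING) | (self.codons > 60)
        if bad.any():
            raise ValidationError("codon indices must be in 0..60 or MISSING")

    @property
    def n_sequences(self):
        return self.codons.shape[0]

    @property
    def n_codon_sites(self):
        return self.codons.shape[1]

    def row(self, seq_id):
        return self.codons[self.sequence_ids.index(seq_id)]

    @classmethod
    def from_sequences(cls, mapping: dict[str, str]) -> "CodonAlignment":
        """Build from id -> in-frame nucleotide strings (aligned, same length)."""
        ids = list(mapping)
        lengths = {len(s) for s in mapping.values()}
        if len(lengths) != 1:
            raise ValidationError("sequences differ in length")
        (L,) = lengths
        if L % 3:
            raise ValidationError("sequence length not divisible by 3")
        n_sites = L // 3
        mat = np.full((len(ids), n_sites), MISSING, dtype=np.int16)
        for i, sid in enumerate(ids):
            seq = mapping[sid].upper().replace("U", "T")
            for s in range(n_sites):
                triplet = seq[3 * s : 3 * s + 3]
                if triplet in CODON_INDEX:
                    mat[i, s] = CODON_INDEX[triplet]
                elif triplet in STOP_CODONS:
                    logger.warning(
                        "stop codon %s at codon site %d of %s treated as missing",
                        triplet, s + 1, sid,
                    )
        return cls(ids, mat)

    def to_fasta(self) -> str:
        chunks = []
        for i, sid in enumerate(self.sequence_ids):
            seq = "".join(
                CODONS[c] if c != MISSING else "---" for c in self.codons[i]
            )
            chunks.append(f">{sid}\n{seq}\n")
        return "".join(chunks)


def read_codon_fasta(source) -> CodonAlignment:
    """Read an in-frame coding-sequence FASTA into a :class:`CodonAlignment`.

    ``source`` may be a path, an open handle, or FASTA text itself.
    Triplets containing gaps, ambiguity codes or stops become MISSING
    (stops log a warning). A sequence whose length is not a multiple of 3,
    or a duplicated id, is an error naming the record.
    """
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith(">"):
        handle = open(source)
    else:
        handle = io.StringIO(str(source))
    try:
        mapping: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in mapping:
                raise ValidationError(f"duplicate sequence id {rec.id!r}")
            seq = str(rec.seq)
            if len(seq) % 3:
                raise ValidationError(
                    f"length of record {rec.id!r} ({len(seq)}) is not divisible by 3"
                )
            mapping[rec.id] = seq
    finally:
        if handle is not source:
            handle.close()
    if not mapping:
        raise ValidationError("no FASTA records found")
    lengths = {len(s) for s in mapping.values()}
    if len(lengths) != 1:
        raise ValidationError("sequences differ in length; input is not an alignment")
    return CodonAlignment.from_sequences(mapping)


# ---------------------------------------------------------------------------
# Trait tables


TRAIT_COLUMNS = [
    "species_id",
    "activity_pattern",
    "site86_residue",
    "site93_residue",
    "sws1_active",
    "is_primate",
    "orbit_convergence",
    "visual_acuity",
]


@dataclass
class TraitTable:
    """Per-species photic trait records.

    Crepuscular activity is normalized to nocturnal on load (the two are
    treated as one scotopic category); the normalization is idempotent.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data.copy()
        for col in TRAIT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("orbit_convergence", "visual_acuity") else None
        df["activity_pattern"] = (
            df["activity_pattern"].fillna("unknown").astype(str).str.strip().str.lower()
        )
        df.loc[df["activity_pattern"] == "crepuscular", "activity_pattern"] = "nocturnal"
        bad = ~df["activity_pattern"].isin(ACTIVITY_PATTERNS)
        if bad.any():
            raise ValidationError(
                f"unknown activity categories: {sorted(df.loc[bad, 'activity_pattern'].unique())}"
            )
        if df["species_id"].isna().any() or (df["species_id"].astype(str) == "").any():
            raise ValidationError("species_id must be non-empty")
        if df["species_id"].duplicated().any():
            dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        for col in ("sws1_active", "is_primate"):
            df[col] = df[col].map(_to_bool)
        for col, (lo, hi) in {
            "orbit_convergence": (0.0, 180.0),
            "visual_acuity": (0.0, np.inf),
        }.items():
            vals = pd.to_numeric(df[col], errors="coerce")
            present = vals.notna()
            if ((vals[present] < lo) | (vals[present] > hi)).any() or (
                col == "visual_acuity" and (vals[present] <= 0).any()
            ):
                raise ValidationError(f"{col} out of range")
            df[col] = vals
        self.data = df.reset_index(drop=True)

    @property
    def species(self):
        return self.data["species_id"].tolist()

    def __len__(self):
        return len(self.data)


def _to_bool(x):
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t", "active"):
        return True
    if s in ("false", "0", "no", "f", "inactive"):
        return False
    if s in ("", "na", "nan", "none"):
        return None
    raise ValidationError(f"cannot interpret boolean value {x!r}")


def read_trait_table(source) -> TraitTable:
    """Read a UTF-8, comma-separated, headered trait CSV."""
    df = pd.read_csv(source)
    if "species_id" not in df.columns:
        raise ValidationError("trait CSV must have a 'species_id' column")
    return TraitTable(df)
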