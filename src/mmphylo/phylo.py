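"""Trees and alignments: parsing, validation, writing.

Trees are rooted with branch lengths in expected substitutions per site.
Because a Markov-modulated process is in general non-reversible, the root
placement matters: input newick is interpreted as rooted at its outermost
node, and explicitly unrooted input (``[&U]``) is rejected with a hint to
root via an outgroup. Internally a tree is flattened to parent/child index
arrays in postorder, which is what the likelihood, simulation and
reconstruction engines iterate over.

Alignments accept FASTA, PHYLIP (sequential or interleaved) and the data
block of a NEXUS file. IUPAC ambiguity codes and the gap character are
mapped to the set of compatible states; a gap is fully ambiguous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO

from .errors import DataParseError, ValidationError

#: IUPAC nucleotide ambiguity codes -> compatible states
IUPAC_NUC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "X": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT",
}


@dataclass
class Tree:
    """A rooted tree flattened to arrays.

    Nodes are indexed 0..n_nodes-1 in a postorder (children before
    parents; the root is last). ``parent[root] == -1``. Tips are the nodes
    with no children; ``tip_labels[i]`` labels node ``tip_nodes[i]``.
    """

    parent: np.ndarray
    children: list[list[int]]
    branch_lengths: np.ndarray  # length of the edge above each node; root: 0
    tip_nodes: np.ndarray
    tip_labels: list[str]
    node_names: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self):
        return range(self.n_nodes - 1, -1, -1)

    def edges(self):
        """(child_node, branch_length) for every non-root node."""
        for v in range(self.n_nodes - 1):
            yield v, float(self.branch_lengths[v])

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths[:-1].sum())

    def is_tip(self, v: int) -> bool:
        return not self.children[v]


def read_tree(text_or_path: str) -> Tree:
    """Parse a rooted newick tree with branch lengths.

    Accepts either a newick string or a path to a file containing one.
    """
    text = text_or_path
    if "(" not in text:
        try:
            with open(text_or_path) as fh:
                text = fh.read()
        except OSError as exc:
            raise DataParseError(f"cannot read tree: {exc}") from exc
    stripped = text.strip()
    if stripped.upper().startswith("[&U]"):
        raise ValidationError(
            "unrooted trees are not supported: the compound process is "
            "generally non-reversible, so root the tree (e.g. on an outgroup)"
        )
    schema = "nexus" if stripped.upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text, schema=schema,
            suppress_internal_node_taxa=False,
            rooting="default-rooted",
        )
    except Exception as exc:  # dendropy raises assorted error types
        if "Duplicate taxon labels" in str(exc):
            raise DataParseError(f"duplicate tip label in newick: {exc}") from exc
        raise DataParseError(f"newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes = list(dtree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    tip_nodes, tip_labels, node_names = [], [], []
    seen = set()
    for i, node in enumerate(nodes):
        if node.parent_node is not None:
            parent[i] = index[id(node.parent_node)]
            children[parent[i]].append(i)
            if node.edge.length is None:
                raise DataParseError(
                    f"missing branch length above node {_node_label(node) or i}"
                )
            if node.edge.length < 0 or not np.isfinite(node.edge.length):
                raise ValidationError(
                    f"branch length above node {_node_label(node) or i} must be "
                    "finite and nonnegative"
                )
            blen[i] = float(node.edge.length)
        label = _node_label(node)
        if node.is_leaf():
            if not label:
                raise DataParseError(f"tip without a label (node index {i})")
            if label in seen:
                raise DataParseError(f"duplicate tip label {label!r}")
            seen.add(label)
            tip_nodes.append(i)
            tip_labels.append(label)
            node_names.append(label)
        else:
            node_names.append(label or f"node{i}")
    # children were appended in child-postorder, restore left-to-right order
    for i, node in enumerate(nodes):
        children[i] = [index[id(c)] for c in node.child_nodes()]
    return Tree(parent, children, blen, np.array(tip_nodes), tip_labels, node_names)


def _node_label(node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


def write_tree(tree: Tree, *, precision: int = 12) -> str:
    """Serialize back to newick with branch lengths at full precision."""

    def render(v: int) -> str:
        if tree.is_tip(v):
            body = tree.node_names[v]
        else:
            body = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return body
        return f"{body}:{tree.branch_lengths[v]:.{precision}g}"

    return render(tree.root) + ";"


def random_tree(n_taxa: int, rng: np.random.Generator, *,
                mean_branch_length: float = 0.2,
                labels: list[str] | None = None) -> Tree:
    """Random rooted bifurcating tree with exponential branch lengths.

    Topology is built by sequential random joins (a Yule-like shape); used
    by the simulator's benchmark panels and the test-suite.
    """
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    parts = [f"{lab}" for lab in labels]
    while len(parts) > 1:
        i, j = rng.choice(len(parts), size=2, replace=False)
        bi = rng.exponential(mean_branch_length)
        bj = rng.exponential(mean_branch_length)
        merged = f"({parts[i]}:{bi:.6f},{parts[j]}:{bj:.6f})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return read_tree(parts[0] + ";")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A rectangular character matrix with IUPAC ambiguity support."""

    taxa: list[str]
    sequences: list[str]
    alphabet: tuple[str, ...] = ("A", "C", "G", "T")
    ambiguity: dict = field(default_factory=lambda: dict(IUPAC_NUC))

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValidationError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {', '.join(dupes)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def tip_partials(self, *, on_unknown: str = "error") -> np.ndarray:
        """0/1 indicator array of shape (n_taxa, n_sites, S).

        Entry (t, l, s) is 1 when character state s is compatible with the
        observed symbol; ambiguity codes and gaps light multiple states.
        ``on_unknown`` is ``"error"`` or ``"ambiguous"`` for symbols outside
        the alphabet and ambiguity table.
        """
        s_count = len(self.alphabet)
        state_idx = {c: i for i, c in enumerate(self.alphabet)}
        lut = {}
        for sym, states in self.ambiguity.items():
            mask = np.zeros(s_count)
            for c in states:
                if c in state_idx:
                    mask[state_idx[c]] = 1.0
            lut[sym] = mask
        for c in self.alphabet:
            lut.setdefault(c, None)
            m = np.zeros(s_count)
            m[state_idx[c]] = 1.0
            lut[c] = m
        out = np.zeros((self.n_taxa, self.n_sites, s_count))
        for t, seq in enumerate(self.sequences):
            for l, sym in enumerate(seq):
                mask = lut.get(sym)
                if mask is None:
                    if on_unknown == "ambiguous":
                        mask = np.ones(s_count)
                    else:
                        raise ValidationError(
                            f"unknown symbol {sym!r} in sequence {self.taxa[t]!r} "
                            f"site {l + 1}"
                        )
                out[t, l] = mask
        return out


_FORMAT_MAP = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


def read_alignment(path_or_text, fmt: str = "fasta", **kwargs) -> Alignment:
    """Read an alignment in FASTA, PHYLIP, or NEXUS (data block) format."""
    fmt = fmt.lower()
    if fmt not in _FORMAT_MAP:
        raise DataParseError(f"unknown alignment format {fmt!r}")
    text = path_or_text
    if isinstance(text, str) and "\n" not in text:
        try:
            with open(text) as fh:
                text = fh.read()
        except OSError as exc:
            raise DataParseError(f"cannot read alignment: {exc}") from exc
    try:
        records = AlignIO.read(io.StringIO(text), _FORMAT_MAP[fmt])
    except Exception as exc:
        raise DataParseError(f"{fmt} parse error: {exc}") from exc
    taxa = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return Alignment(taxa, seqs, **kwargs)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for t, s in zip(aln.taxa, aln.sequences):
            fh.write(f">{t}\n{s}\n")


def match_tree_alignment(tree: Tree, aln: Alignment) -> np.ndarray:
    """Validate that tip labels and taxa coincide (case-sensitive).

    Returns ``order`` with ``order[i]`` the alignment row for tip ``i`` of
    ``tree.tip_labels``. Missing or extra taxa are listed by name.
    """
    tip_set, taxa_set = set(tree.tip_labels), set(aln.taxa)
    missing = sorted(tip_set - taxa_set)
    extra = sorted(taxa_set - tip_set)
    if missing or extra:
        parts = []
        if missing:
            parts.append("missing from alignment: " + ", ".join(missing))
        if extra:
            parts.append("not in tree: " + ", ".join(extra))
        raise ValidationError("tree/alignment mismatch — " + "; ".join(parts))
    row = {t: i for i, t in enumerate(aln.taxa)}
    return np.array([row[lab] for lab in tree.tip_labels])
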