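"""Rooted reference phylogeny with lineage annotations.

The tree's leaves are the taxa (OTUs) of the reference database. Besides
wrapping a :class:`skbio.TreeNode`, this module compiles the tree once into
flat arrays — a post-order traversal plan — so that the community similarity
kernel can be evaluated against many database samples with vectorized numpy
operations instead of per-pair tree recursion.

The canonical leaf ordering used everywhere (dense abundance vectors, the
per-sample store, index construction) is the post-order in which leaves are
encountered; it is fixed at build time and recorded in the store manifest.
"""

from __future__ import annotations

import io
import math

import numpy as np
from skbio import TreeNode

from .errors import ValidationError

#: Ranked taxonomy levels understood by lineage strings.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))

UNCLASSIFIED = "unclassified"


def parse_lineage(lineage: str, rank: str) -> str:
    """Extract the label at `rank` from a semicolon-delimited lineage string.

    Missing ranks and empty labels (a bare prefix such as ``g__``) pool into
    the ``"unclassified"`` key.
    """
    if rank not in RANK_PREFIXES:
        raise ValidationError(f"unknown taxonomy rank: {rank!r} (expected one of {RANKS})")
    prefix = RANK_PREFIXES[rank]
    for field in str(lineage).split(";"):
        field = field.strip()
        if field.startswith(prefix):
            label = field[len(prefix):].strip()
            return label if label else UNCLASSIFIED
    return UNCLASSIFIED


class PhylogenyView:
    """A rooted tree with branch lengths plus per-leaf lineage strings.

    Parameters
    ----------
    tree:
        Rooted ``skbio.TreeNode`` whose tips carry unique names. Branch
        lengths must be finite and non-negative; a missing length is read
        as 0 (common for the root edge).
    lineages:
        Mapping leaf name -> lineage string (``k__...;p__...;...``). May be
        empty when only similarity computations are needed.
    """

    def __init__(self, tree: TreeNode, lineages: dict[str, str] | None = None):
        self.tree = tree
        self.lineages = dict(lineages or {})
        self._compile()
        self._decay_cache: dict[float, list[np.ndarray]] = {}

    # ------------------------------------------------------------------
    def _compile(self) -> None:
        leaf_names: list[str] = []
        leaf_ids: list[int] = []
        internal: list[tuple[int, np.ndarray, np.ndarray]] = []
        node_id: dict[int, int] = {}

        for i, node in enumerate(self.tree.postorder(include_self=True)):
            node_id[id(node)] = i
            length = node.length
            if length is None:
                length = 0.0
            if not math.isfinite(length) or length < 0:
                raise ValidationError(
                    f"branch length of node {node.name!r} must be finite and >= 0, got {length}"
                )
            if node.is_tip():
                if node.name is None:
                    raise ValidationError("every leaf must be named")
                leaf_names.append(node.name)
                leaf_ids.append(i)
            else:
                kids = node.children
                child_ids = np.array([node_id[id(c)] for c in kids], dtype=np.intp)
                child_lengths = np.array(
                    [0.0 if c.length is None else float(c.length) for c in kids]
                )
                internal.append((i, child_ids, child_lengths))

        if len(set(leaf_names)) != len(leaf_names):
            dupes = sorted({n for n in leaf_names if leaf_names.count(n) > 1})
            raise ValidationError(f"duplicate leaf names in tree: {dupes[:5]}")

        self.n_nodes = len(node_id)
        self.leaf_order: tuple[str, ...] = tuple(leaf_names)
        self.leaf_index: dict[str, int] = {n: k for k, n in enumerate(leaf_names)}
        self._leaf_node_ids = np.array(leaf_ids, dtype=np.intp)
        self._internal = internal

    # ------------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def decay_factors(self, decay_rate: float) -> list[np.ndarray]:
        """Per-internal-node arrays of exp(-lambda * child branch length)."""
        key = float(decay_rate)
        if key not in self._decay_cache:
            self._decay_cache[key] = [
                np.exp(-key * lengths) for (_u, _kids, lengths) in self._internal
            ]
        return self._decay_cache[key]

    def rank_labels(self, rank: str) -> list[str]:
        """Per-leaf labels at `rank`, in canonical leaf order."""
        return [
            parse_lineage(self.lineages.get(name, ""), rank) for name in self.leaf_order
        ]

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(
        cls, newick: str, lineages: dict[str, str] | None = None
    ) -> "PhylogenyView":
        """Build from a newick string or a path to a newick file."""
        text = newick
        if "(" not in newick:  # looks like a path, not a tree
            with open(newick) as fh:
                text = fh.read()
        tree = TreeNode.read(io.StringIO(text))
        return cls(tree, lineages)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhylogenyView: {self.n_leaves} leaves, {self.n_nodes} nodes>"
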