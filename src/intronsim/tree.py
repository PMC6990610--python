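"""Guide-tree data model, Newick I/O, ladder layout, and the fixture tree.

The simulators run on a *rooted display of an unrooted binary tree*: with N
leaves there are N-2 internal "ancestral sequence" nodes, the display root
(``AS_1``) carries a basal trifurcation, and every other internal node is
binary.  For N=14 that gives the 12 ancestral nodes AS_1...AS_12.

The ladder layout is the deterministic drawing convention behind the
topology score: at every internal node children are ordered by descendant
leaf count (larger clade first; ties broken by the lexicographically
smallest descendant leaf label), leaves then occupy rows 0..N-1 from top to
bottom, and each internal node sits at the mean row of its children.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import skbio

__all__ = [
    "TreeNode",
    "GuideTree",
    "LadderLayout",
    "NewickError",
    "StructureError",
    "parse_newick",
    "write_newick",
    "ladderize",
    "fixture_tree",
]


class NewickError(ValueError):
    """Malformed Newick text."""


class StructureError(ValueError):
    """A tree violating the rooted-display structural contract."""


@dataclass
class TreeNode:
    """One node of a guide tree; ``branch_length`` is the edge to the parent."""

    label: str
    branch_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_count(self) -> int:
        return len(self.leaves())


_LABEL_LENGTH = re.compile(r"^(.*?)(\d+)$")


def _length_from_label(label: str) -> int | None:
    m = _LABEL_LENGTH.match(label)
    if m and m.group(1) and not m.group(1).startswith("AS"):
        return int(m.group(2))
    return None


@dataclass
class GuideTree:
    """A rooted-display tree plus the per-leaf target-length table."""

    root: TreeNode
    leaf_specs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [leaf.label for leaf in self.root.leaves()]
        if len(labels) != len(set(labels)):
            raise StructureError("leaf labels must be unique")
        if not self.leaf_specs:
            self.leaf_specs = {
                lab: ln
                for lab in labels
                if (ln := _length_from_label(lab)) is not None
            }

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if not n.is_leaf]

    def edges(self):
        """Yield (parent, child) over all branches in preorder."""
        for node in self.root.preorder():
            for child in node.children:
                yield node, child


def parse_newick(text: str, expected_leaves: int | None = None) -> GuideTree:
    """Parse Newick text into a :class:`GuideTree`.

    Internal labels are preserved; internal nodes lacking a label are named
    ``AS_k`` in preorder.  Round-trips through :func:`write_newick`.
    """
    try:
        sk = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse errors
        raise NewickError(f"cannot parse Newick text: {exc}") from exc

    def convert(node) -> TreeNode:
        length = None if node.length is None else float(node.length)
        return TreeNode(
            label=node.name or "",
            branch_length=length,
            children=[convert(c) for c in node.children],
        )

    root = convert(sk)
    taken = {n.label for n in root.preorder() if n.label}
    k = 1
    for node in root.preorder():
        if not node.is_leaf and not node.label:
            while f"AS_{k}" in taken:
                k += 1
            node.label = f"AS_{k}"
            taken.add(node.label)
    tree = GuideTree(root)
    if expected_leaves is not None and tree.n_leaves != expected_leaves:
        raise StructureError(
            f"expected {expected_leaves} leaves, found {tree.n_leaves}"
        )
    return tree


def _newick_node(node: TreeNode, is_root: bool) -> str:
    if node.is_leaf:
        s = node.label
    else:
        inner = ",".join(_newick_node(c, False) for c in node.children)
        s = f"({inner}){node.label}"
    if not is_root and node.branch_length is not None:
        s += f":{node.branch_length:.10g}"
    return s


def write_newick(tree: GuideTree) -> str:
    """Serialise with branch lengths and internal labels retained."""
    return _newick_node(tree.root, True) + ";"


@dataclass
class LadderLayout:
    """Canonical drawing of a tree: leaf rows and per-leaf branch geometry."""

    leaf_order: list[str]
    leaf_row: dict[str, int]
    leaf_parent_row: dict[str, float]
    node_row: dict[str, float]

    def to_records(self) -> list[dict]:
        return [
            {
                "leaf": lab,
                "row": self.leaf_row[lab],
                "parent_row": self.leaf_parent_row[lab],
            }
            for lab in self.leaf_order
        ]


def _min_leaf_label(node: TreeNode) -> str:
    return min(leaf.label for leaf in node.leaves())


def ladderize(tree: GuideTree, convention: str = "larger-first") -> LadderLayout:
    """Pure, deterministic layout of ``tree`` (no RNG, insensitive to input
    child order)."""
    if convention not in ("larger-first", "smaller-first"):
        raise ValueError(f"unknown convention {convention!r}")
    sign = -1 if convention == "larger-first" else 1

    leaf_order: list[str] = []
    node_row: dict[str, float] = {}
    leaf_parent_row: dict[str, float] = {}

    def place(node: TreeNode) -> float:
        if node.is_leaf:
            row = float(len(leaf_order))
            leaf_order.append(node.label)
            node_row[node.label] = row
            return row
        ordered = sorted(
            node.children, key=lambda c: (sign * c.leaf_count, _min_leaf_label(c))
        )
        rows = [place(c) for c in ordered]
        row = float(np.mean(rows))
        node_row[node.label] = row
        return row

    place(tree.root)
    for node, child in tree.edges():
        if child.is_leaf:
            leaf_parent_row[child.label] = node_row[node.label]
    leaf_row = {lab: i for i, lab in enumerate(leaf_order)}
    return LadderLayout(leaf_order, leaf_row, leaf_parent_row, node_row)


#: Species abbreviations of the default 14-leaf fixture, positioned along the
#: caterpillar backbone: two basal leaves, one leaf per intermediate ancestor,
#: two leaves on the last ancestor.
_FIXTURE_ABBREVS = (
    "Bf", "Bb",             # basal trifurcation (lancelets)
    "Cm", "Ch", "Xl", "Xt", "Cp", "Cy", "Gg", "Rt", "Ac", "Hs",
    "Mm", "Am",             # cherry on the last ancestor
)

#: Printed target lengths anchoring the fixture: shortest (whale shark),
#: the worked elephant-shark example, and longest (Mexican tetra).
FIXTURE_ANCHORS = {"Rt": 112, "Cm": 376, "Am": 1975}


def fixture_tree(
    seed: int = 0,
    n_leaves: int = 14,
    branch_length_range: tuple[float, float] = (0.05, 0.60),
    leaf_length_range: tuple[int, int] = (150, 1850),
) -> GuideTree:
    """A ladder-like rooted-display guide tree with target-length leaf specs.

    For the default ``n_leaves=14`` the leaves carry chordate species
    abbreviations; three lengths are anchored to the printed values
    (Rt112, Cm376, Am1975) and the remaining eleven are drawn uniformly from
    ``leaf_length_range``, which is chosen so that both the
    mutation-and-deletion validity bound (every ancestor longer than its
    leaves at the shortest-ancestor length 2000) and the
    mutation-and-insertion bound (every ancestor shorter than its leaves at
    the longest-ancestor length 140) hold.  Other leaf counts use generic
    labels with all lengths drawn.
    """
    if n_leaves < 4:
        raise StructureError("fixture requires at least 4 leaves")
    rng = np.random.default_rng(seed)
    if n_leaves == 14:
        abbrevs = list(_FIXTURE_ABBREVS)
        anchors = dict(FIXTURE_ANCHORS)
    else:
        # two-letter abbreviations so the trailing digits of a label are
        # unambiguously the target length
        abbrevs = [
            f"{chr(ord('A') + i // 26)}{chr(ord('a') + i % 26)}"
            for i in range(n_leaves)
        ]
        anchors = {}

    lengths = {}
    for ab in abbrevs:
        if ab in anchors:
            lengths[ab] = anchors[ab]
        else:
            lengths[ab] = int(rng.integers(leaf_length_range[0], leaf_length_range[1] + 1))
    labels = {ab: f"{ab}{lengths[ab]}" for ab in abbrevs}

    def bl() -> float:
        return float(rng.uniform(*branch_length_range))

    def leaf(ab: str) -> TreeNode:
        return TreeNode(labels[ab], bl())

    n_internal = n_leaves - 2
    # caterpillar: AS_1 holds two leaves + AS_2; AS_k one leaf + AS_{k+1};
    # AS_{n-2} ends in a cherry.
    root = TreeNode("AS_1", None, [leaf(abbrevs[0]), leaf(abbrevs[1])])
    current = root
    for k in range(2, n_internal):
        nxt = TreeNode(f"AS_{k}", bl(), [leaf(abbrevs[k])])
        current.children.append(nxt)
        current = nxt
    last = TreeNode(
        f"AS_{n_internal}", bl(), [leaf(abbrevs[-2]), leaf(abbrevs[-1])]
    )
    current.children.append(last)
    return GuideTree(root, {labels[ab]: lengths[ab] for ab in abbrevs})
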