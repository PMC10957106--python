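"""Time-calibrated trees and the surgery used to assemble and dissect them.

A :class:`TimeTree` is a rooted tree with branch lengths in millions of years
(Ma) and, for almost every analysis here, an ultrametric shape: all tips lie
at the present (age 0) and every internal node has a well-defined age in Ma
before present.  The module provides

* Newick round-tripping (parsing delegated to dendropy),
* grafting of rescaled subtrees onto a dated backbone (the "metachronogram"
  construction used to combine a well-dated backbone with densely sampled
  clade-level trees),
* expansion of genera into polytomies at the genus crown node,
* time-slicing: collapsing everything younger than a cutoff so that turnover
  can be measured among the lineages present at a past time.

Ages are stored implicitly: they are recomputed from branch lengths on
demand, with tips at exactly 0 and the root at the maximum root-to-tip path
length.  The ultrametricity tolerance used throughout is 1e-6 Ma.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy

ULTRAMETRIC_TOL = 1e-6

__all__ = [
    "Node",
    "TimeTree",
    "GraftInstruction",
    "TreeError",
    "graft_subtree",
    "expand_genus_polytomies",
    "slice_tree_at",
    "node_ages",
    "check_ultrametric",
]


class TreeError(ValueError):
    """Raised for structurally invalid tree operations."""


class Node:
    """A node in a rooted tree.

    ``length`` is the length of the branch subtending the node (0.0 for the
    root).  ``name`` doubles as the branch identifier of the subtending
    branch; internal nodes get stable auto-generated names.
    """

    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: "Node | None" = None
        self.children: list["Node"] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, length={self.length:g})"


class TimeTree:
    """Rooted, dated tree; branch lengths in Ma; unique tip labels."""

    def __init__(self, root: Node):
        self.root = root
        self.root.parent = None
        self.root.length = 0.0
        self._ensure_names()
        labels = [t.name for t in self.tips()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    # ------------------------------------------------------------------ #
    # traversal & bookkeeping
    # ------------------------------------------------------------------ #
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips()]

    def find(self, name: str) -> Node:
        for n in self.preorder():
            if n.name == name:
                return n
        raise TreeError(f"node {name!r} not found")

    def _ensure_names(self) -> None:
        """Give every node a unique name (internal nodes: stable preorder
        auto-names; colliding internal names are re-assigned)."""
        taken: set[str] = set()
        unnamed: list[Node] = []
        for n in self.preorder():
            if n.name is None or (n.name in taken and not n.is_leaf):
                n.name = None
                unnamed.append(n)
            else:
                taken.add(n.name)
        i = 0
        for n in unnamed:
            while f"n{i}" in taken:
                i += 1
            n.name = f"n{i}"
            taken.add(n.name)

    # ------------------------------------------------------------------ #
    # ages
    # ------------------------------------------------------------------ #
    def depths(self) -> dict[str, float]:
        """Distance of every node from the root."""
        depth: dict[str, float] = {self.root.name: 0.0}
        for n in self.preorder():
            if n.parent is not None:
                depth[n.name] = depth[n.parent.name] + n.length
        return depth

    def ages(self) -> dict[str, float]:
        """Ages in Ma before present; the deepest tip defines the present."""
        depth = self.depths()
        height = max(depth[t.name] for t in self.tips())
        return {name: height - d for name, d in depth.items()}

    @property
    def root_age(self) -> float:
        return self.ages()[self.root.name]

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        depth = self.depths()
        tip_depths = [depth[t.name] for t in self.tips()]
        return max(tip_depths) - min(tip_depths) <= tol

    def mrca(self, labels) -> Node:
        """Most recent common ancestor of the given tip labels."""
        want = set(labels)
        missing = want - set(self.tip_labels())
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        below: dict[str, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n.name] = {n.name} if n.name in want else set()
            else:
                below[n.name] = set().union(*(below[c.name] for c in n.children))
            if below[n.name] == want:
                return n
        raise TreeError("MRCA not found")  # pragma: no cover

    def tip_sets(self) -> dict[str, frozenset[str]]:
        """Descendant tip-label set for every node."""
        out: dict[str, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                out[n.name] = frozenset([n.name])
            else:
                s: set[str] = set()
                for c in n.children:
                    s |= out[c.name]
                out[n.name] = frozenset(s)
        return out

    # ------------------------------------------------------------------ #
    # copy / prune
    # ------------------------------------------------------------------ #
    def copy(self) -> "TimeTree":
        def clone(n: Node) -> Node:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return TimeTree(clone(self.root))

    def remove_tips(self, labels) -> "TimeTree":
        """Return a copy with the given tips pruned.

        Unifurcations left behind are suppressed (branch lengths added); the
        root is re-seated if it ends up with a single child.
        """
        drop = set(labels)
        keep = [t for t in self.tip_labels() if t not in drop]
        if not keep:
            raise TreeError("cannot remove all tips")
        missing = drop - set(self.tip_labels())
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")

        def build(n: Node) -> Node | None:
            if n.is_leaf:
                if n.name in drop:
                    return None
                return Node(n.name, n.length)
            kids = [k for k in (build(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += n.length
                return kids[0]
            m = Node(n.name, n.length)
            for k in kids:
                m.add_child(k)
            return m

        new_root = build(self.root)
        assert new_root is not None
        new_root.length = 0.0
        return TimeTree(new_root)

    # ------------------------------------------------------------------ #
    # Newick I/O
    # ------------------------------------------------------------------ #
    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            node = Node(label, length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self, precision: int = 10) -> str:
        fmt = f"%.{precision}g"

        def write(n: Node, out: io.StringIO, is_root: bool) -> None:
            if n.children:
                out.write("(")
                for i, c in enumerate(n.children):
                    if i:
                        out.write(",")
                    write(c, out, False)
                out.write(")")
            if n.is_leaf or not n.name.startswith("n"):
                out.write(n.name or "")
            if not is_root:
                out.write(":" + fmt % n.length)

        buf = io.StringIO()
        write(self.root, buf, True)
        buf.write(";")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path) -> "TimeTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.3f})"


# ---------------------------------------------------------------------- #
# free-function conveniences mirroring the module surface
# ---------------------------------------------------------------------- #
def node_ages(tree: TimeTree) -> dict[str, float]:
    return tree.ages()


def check_ultrametric(tree: TimeTree, tol: float = ULTRAMETRIC_TOL) -> bool:
    return tree.is_ultrametric(tol)


@dataclass
class GraftInstruction:
    """Replace a set of backbone tips with a dated subtree.

    The attachment point is the MRCA of ``tips_to_replace`` when there are
    several (a crown graft), or the midpoint of the terminal branch when a
    single backbone tip stands in for the whole clade.
    """

    subtree: TimeTree
    tips_to_replace: frozenset[str] = field(default_factory=frozenset)
    attachment: str | None = None  # explicit backbone internal node, optional

    def __post_init__(self):
        self.tips_to_replace = frozenset(self.tips_to_replace)
        if not self.tips_to_replace:
            raise TreeError("tips_to_replace must be non-empty")
        if self.subtree.n_tips < 1:
            raise TreeError("subtree must have at least one tip")


def _rescale(tree: TimeTree, factor: float) -> TimeTree:
    out = tree.copy()
    for n in out.preorder():
        n.length *= factor
    return out


def graft_subtree(backbone: TimeTree, instr: GraftInstruction) -> TimeTree:
    """Graft a rescaled subtree onto the backbone in place of some tips.

    The subtree is uniformly rescaled so that its crown age equals the
    attachment age (MRCA age of the replaced tips, or half the terminal
    branch for a single replaced tip), then substituted for them.  When the
    replaced tips are paraphyletic the subtree is attached at their MRCA
    with a zero-length stem and the stragglers are simply pruned.
    """
    if not backbone.is_ultrametric():
        raise TreeError("backbone is not ultrametric")
    if instr.subtree.n_tips > 1 and not instr.subtree.is_ultrametric():
        raise TreeError("subtree is not ultrametric")
    clash = set(instr.subtree.tip_labels()) & (
        set(backbone.tip_labels()) - set(instr.tips_to_replace)
    )
    if clash:
        raise TreeError(f"duplicate tip labels after grafting: {sorted(clash)}")

    ages = backbone.ages()
    tips = instr.tips_to_replace
    single = instr.attachment is None and len(tips) == 1

    if instr.attachment is not None:
        att_age = ages[backbone.find(instr.attachment).name]
    elif single:
        tip_node = backbone.find(next(iter(tips)))
        att_age = tip_node.length / 2.0  # halfway along the terminal branch
    else:
        att_age = ages[backbone.mrca(tips).name]
    if att_age <= 0:
        raise TreeError("attachment age must be positive")

    # rescale the subtree so its crown sits at the attachment age
    if instr.subtree.n_tips == 1:
        # degenerate subtree: a single new tip hanging from the attachment
        scaled = Node(instr.subtree.tips()[0].name, att_age)
    else:
        crown = instr.subtree.root_age
        if crown <= 0:
            raise TreeError("subtree crown age must be positive (rescale factor <= 0)")
        scaled = _rescale(instr.subtree, att_age / crown).root

    work = backbone.copy()
    w_ages = work.ages()

    if single:
        target = work.find(next(iter(tips)))
        parent = target.parent
        if parent is None:
            raise TreeError("cannot graft onto a single-tip backbone")
        stem = Node(None, target.length - att_age)
        parent.children[parent.children.index(target)] = stem
        stem.parent = parent
        _attach_subtree(stem, scaled)
        return TimeTree(work.root)

    # crown graft: hang the rescaled subtree from the MRCA with a
    # zero-length stem, then prune the replaced tips.  If the replaced tips
    # were monophyletic the MRCA is left unifurcating and the stem absorbs
    # its branch; if paraphyletic the stem stays at the MRCA.  Both cases
    # preserve ultrametricity.
    if instr.attachment is not None:
        mrca = work.find(instr.attachment)
    else:
        mrca = work.mrca(tips)
    stem = Node(None, 0.0)
    _attach_subtree(stem, scaled)
    mrca.add_child(stem)
    return TimeTree(work.root).remove_tips(tips)


def _attach_subtree(stem: Node, sub_root: Node) -> None:
    """Hang a (rescaled) subtree root below ``stem``; stem length is preset."""
    if sub_root.is_leaf:
        stem.name = sub_root.name
        stem.length += sub_root.length
    else:
        for c in sub_root.children:
            stem.add_child(c)
        stem.name = None


def expand_genus_polytomies(
    backbone: TimeTree,
    genus_membership: dict[str, list[str]],
    genus_of_tip: Callable[[str], str] | None = None,
) -> TimeTree:
    """Replace each genus' backbone tips with a species polytomy.

    Genera sampled by several backbone tips get their species attached as a
    polytomy at the genus crown node; genera sampled by a single tip get the
    polytomy halfway along that terminal branch.  Backbone tips are assigned
    to genera by ``genus_of_tip`` (default: the label up to the first
    underscore, or the whole label).
    """
    if genus_of_tip is None:
        genus_of_tip = lambda label: label.split("_")[0]  # noqa: E731

    work = backbone.copy()
    tip_genus = {t: genus_of_tip(t) for t in work.tip_labels()}

    for genus, species in genus_membership.items():
        if not species:
            raise TreeError(f"genus {genus!r} maps to no species")
        members = [t for t, g in tip_genus.items() if g == genus]
        if not members:
            raise TreeError(f"genus {genus!r} not found in backbone")
        if len(species) == 1 and len(members) == 1:
            # relabel only
            work.find(members[0]).name = species[0]
            continue
        if len(members) > 1:
            crown = work.mrca(members)
            crown_age = work.ages()[crown.name]
            clade = work.tip_sets()[crown.name]
            if set(clade) - set(members):
                raise TreeError(f"genus {genus!r} is not monophyletic in backbone")
            crown.children = []
            for sp in species:
                crown.add_child(Node(sp, crown_age))
            crown.name = None
        else:
            tip = work.find(members[0])
            half = tip.length / 2.0
            tip.length = half
            tip.name = None
            for sp in species:
                tip.add_child(Node(sp, half))
        work = TimeTree(work.root)
    return TimeTree(work.root)


def slice_tree_at(
    tree: TimeTree, cutoff_ma: float
) -> tuple[TimeTree, dict[str, frozenset[str]]]:
    """Collapse everything younger than ``cutoff_ma``.

    Every branch alive at the cutoff becomes a single lineage-tip, named
    after its alphabetically first descendant tip; the sliced tree is
    ultrametric with those tips at the cutoff (re-measured as age 0).  The
    returned mapping sends each lineage tip to the original tips it absorbs.
    A cutoff of 0 returns a copy of the input with the identity mapping.
    """
    if cutoff_ma < 0:
        raise TreeError("cutoff must be non-negative")
    if cutoff_ma >= tree.root_age:
        raise TreeError("cutoff must be below the root age")
    if cutoff_ma == 0:
        return tree.copy(), {t: frozenset([t]) for t in tree.tip_labels()}

    ages = tree.ages()
    tipsets = tree.tip_sets()
    mapping: dict[str, frozenset[str]] = {}

    def build(n: Node) -> Node:
        if ages[n.name] > cutoff_ma and not n.is_leaf:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add_child(build(c))
            return m
        # branch crosses the cutoff: becomes a lineage tip
        label = min(tipsets[n.name])
        mapping[label] = tipsets[n.name]
        parent_age = ages[n.parent.name]
        return Node(label, parent_age - cutoff_ma)

    new_root = build(tree.root)
    new_root.length = 0.0
    return TimeTree(new_root), mapping
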