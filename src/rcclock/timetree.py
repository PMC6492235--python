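"""Rooted, strictly bifurcating time trees (chronograms).

A :class:`TimeTree` carries absolute node ages in Ga before present (tips
at 0) and, optionally, per-node evolutionary rates in substitutions per
site per Ga.  Branch durations are ``parent.age - child.age`` and must be
strictly positive.  All taxa are extant, so non-ultrametric Newick input
is rejected rather than silently accommodated.

Newick dialects: plain branch lengths interpreted as durations in Ga, or
the de-facto annotated convention ``[&age=...,rate=...]`` on nodes.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path
from typing import Callable, Iterator, Sequence

import dendropy


class TopologyError(ValueError):
    """Non-binary node, too few tips, or malformed structure."""


class AgeError(ValueError):
    """Negative durations, non-contemporaneous tips, or ordering violations."""


class CladeResolutionError(KeyError):
    """A clade specification does not resolve to a node of the tree."""


class Node:
    """A node of a :class:`TimeTree` (binary; tips carry taxon names)."""

    __slots__ = ("children", "parent", "name", "label", "age", "rate", "index")

    def __init__(
        self,
        name: str | None = None,
        age: float | None = None,
        rate: float | None = None,
        label: str | None = None,
    ) -> None:
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.name = name          # taxon name (tips only)
        self.label = label        # optional clade label (internal nodes)
        self.age = age            # Ga before present
        self.rate = rate          # subs/site/Ga
        self.index: int = -1      # postorder index, set by TimeTree

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        what = self.name or self.label or "node"
        return f"<Node {what} age={self.age} rate={self.rate}>"


class TimeTree:
    """A rooted binary chronogram with postorder-indexed nodes."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self.reindex()
        self._validate_topology()

    # ---- structure -------------------------------------------------

    def reindex(self) -> None:
        """Assign postorder indices (tips first within each subtree)."""
        for i, node in enumerate(self.postorder()):
            node.index = i
        self.nodes: list[Node] = list(self.postorder())

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    @property
    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_tip]

    def _validate_topology(self) -> None:
        tips = self.tips()
        if len(tips) < 2:
            raise TopologyError("a time tree needs at least two tips")
        for node in self.nodes:
            if node.children and len(node.children) != 2:
                raise TopologyError(
                    f"node with {len(node.children)} children; tree must be binary"
                )
        names = [t.name for t in tips]
        if None in names or len(set(names)) != len(names):
            raise TopologyError("tips must carry unique taxon names")

    # ---- ages and rates --------------------------------------------

    def validate_ages(self, require_rates: bool = False) -> None:
        """Enforce the chronogram contract: tips at 0, parent > child, root > 0."""
        if self.root.age is None or self.root.age <= 0:
            raise AgeError("root age must be positive")
        for node in self.nodes:
            if node.age is None:
                raise AgeError("every node needs an age")
            if node.is_tip and abs(node.age) > 1e-9:
                raise AgeError(f"tip {node.name!r} has age {node.age}; tips must be 0")
            for child in node.children:
                if child.age is None or not node.age > child.age:
                    raise AgeError(
                        f"edge with non-positive duration at ages "
                        f"{node.age} -> {child.age}"
                    )
            if require_rates or node.rate is not None:
                if node.rate is None or node.rate <= 0:
                    raise AgeError("rates, when present, must be positive")

    def mrca(self, names: Sequence[str], require_monophyly: bool = False) -> Node:
        """Most recent common ancestor of a set of tip names."""
        want = set(names)
        if not want:
            raise CladeResolutionError("empty clade specification")
        missing = want - set(self.tip_names)
        if missing:
            raise CladeResolutionError(f"unknown tips {sorted(missing)}")
        tipsets = self.tip_sets()
        best: Node | None = None
        for node in self.nodes:  # postorder: first superset is the MRCA
            if want <= tipsets[node.index]:
                best = node
                break
        assert best is not None
        if require_monophyly and tipsets[best.index] != want:
            raise CladeResolutionError(
                f"tips {sorted(want)} are not monophyletic; their MRCA also "
                f"contains {sorted(tipsets[best.index] - want)}"
            )
        return best

    def tip_sets(self) -> list[frozenset[str]]:
        """Per-node tip-name sets, indexed like ``self.nodes``."""
        sets: list[frozenset[str]] = [frozenset()] * len(self.nodes)
        for node in self.nodes:  # postorder
            if node.is_tip:
                sets[node.index] = frozenset([node.name])
            else:
                acc: frozenset[str] = frozenset()
                for child in node.children:
                    acc |= sets[child.index]
                sets[node.index] = acc
        return sets

    def node_key(self, node: Node) -> str:
        """Stable node identifier: short hash of the sorted tip-name set."""
        tipset = self.tip_sets()[node.index]
        digest = hashlib.sha1("|".join(sorted(tipset)).encode()).hexdigest()[:10]
        return f"{node.label}@{digest}" if node.label else digest

    def copy(self) -> "TimeTree":
        def clone(node: Node) -> Node:
            new = Node(name=node.name, age=node.age, rate=node.rate, label=node.label)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return TimeTree(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree {self.n_tips} tips, root age {self.root.age}>"


# ---- Newick I/O ----------------------------------------------------

_ANNOT = re.compile(r"&?\s*([A-Za-z_][\w.]*)\s*=\s*([^,\]]+)")


def _parse_annotations(comments: list[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for comment in comments:
        for key, value in _ANNOT.findall(comment):
            try:
                out[key] = float(value)
            except ValueError:
                continue
    return out


def read_tree(path_or_string: str | Path) -> TimeTree:
    """Read a rooted binary chronogram from Newick.

    Plain Newick: branch lengths are durations in Ga and root-to-tip path
    lengths must agree (contemporaneous tips), otherwise :class:`AgeError`.
    Annotated Newick (``[&age=...]`` comments) takes ages directly.
    """
    text = str(path_or_string)
    if "(" not in text:  # looks like a path, not a Newick string
        text = Path(path_or_string).read_text()
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        extract_comment_metadata=False,
    )

    def build(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(name=name, label=getattr(dnode, "label", None))
        annot = _parse_annotations(dnode.comments or [])
        if "age" in annot:
            node.age = annot["age"]
        if "rate" in annot:
            node.rate = annot["rate"]
        for dchild in dnode.child_nodes():
            node.add_child(build(dchild))
        if not dnode.child_nodes() and name is None:
            raise TopologyError("unnamed tip in Newick input")
        return node

    root = build(dtree.seed_node)
    tree = TimeTree(root)

    annotated = any(n.age is not None for n in tree.nodes)
    if annotated:
        for node in tree.tips():
            if node.age is None:
                node.age = 0.0
        tree.validate_ages()
        return tree

    # plain: reconstruct ages from branch-length durations
    depths: dict[int, float] = {root.index: 0.0}
    dn_by_node: dict[int, object] = {}

    def pair(dnode, node) -> None:
        dn_by_node[node.index] = dnode
        for dchild, child in zip(dnode.child_nodes(), node.children):
            pair(dchild, child)

    pair(dtree.seed_node, root)
    for node in tree.preorder():
        if node is root:
            continue
        edge = dn_by_node[node.index].edge.length
        if edge is None:
            raise AgeError("plain Newick input needs branch lengths on every edge")
        if edge < 0:
            raise AgeError(f"negative branch duration {edge}")
        depths[node.index] = depths[node.parent.index] + edge

    tip_depths = [depths[t.index] for t in tree.tips()]
    span = max(tip_depths)
    if span <= 0:
        raise AgeError("tree has zero total depth")
    if max(tip_depths) - min(tip_depths) > 1e-6 * span:
        raise AgeError(
            "root-to-tip path lengths differ; tips must be contemporaneous "
            f"(spread {max(tip_depths) - min(tip_depths):g} Ga)"
        )
    for node in tree.nodes:
        node.age = 0.0 if node.is_tip else span - depths[node.index]
    tree.validate_ages()
    return tree


def write_annotated_tree(
    tree: TimeTree,
    path: str | Path,
    extra: Callable[[Node], dict[str, float]] | None = None,
) -> None:
    """Write Newick with ``[&age=...,rate=...]`` node annotations.

    ``extra`` may supply additional per-node annotations (e.g. credible
    intervals).  Ages round-trip through :func:`read_tree` to 1e-9 Ga.
    """
    tree.validate_ages()

    def annot(node: Node) -> str:
        fields = [f"age={node.age:.12g}"]
        if node.rate is not None:
            fields.append(f"rate={node.rate:.6g}")
        if extra is not None:
            for key, value in extra(node).items():
                fields.append(f"{key}={value:.6g}")
        return "[&" + ",".join(fields) + "]"

    def newick(node: Node) -> str:
        if node.is_tip:
            core = node.name
        else:
            core = "(" + ",".join(newick(c) for c in node.children) + ")"
            if node.label:
                core += node.label
        length = "" if node.parent is None else f":{node.parent.age - node.age:.12g}"
        return core + annot(node) + length

    Path(path).write_text(newick(tree.root) + ";\n")
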