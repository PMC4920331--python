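"""Sampled-ancestor time-trees.

A :class:`SampledTree` is a rooted binary time-tree whose tips are
extant species (age 0) or fossils (age > 0), with node ages in Myr
before present.  A fossil that is a direct ancestor of other samples (a
*sampled ancestor*) is encoded, as in BEAST-style Newick, as a tip
attached by a zero-length branch to a degree-two attachment point made
binary: the attachment node has the fossil tip (branch length 0) as one
child and the descendant subtree as the other.  The origin time of the
birth-death process, ``origin_T``, sits above the root.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Node", "SampledTree", "ExplosionError"]


class ExplosionError(RuntimeError):
    """A forward simulation exceeded the lineage cap."""


class Node:
    __slots__ = ("age", "children", "parent", "label", "kind")

    def __init__(
        self,
        age: float,
        kind: str = "internal",
        label: str | None = None,
    ) -> None:
        self.age = age
        self.kind = kind  # internal | extant | fossil
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_sampled_ancestor(self) -> bool:
        """True for a fossil tip sitting at its attachment point (zero branch)."""
        return (
            self.kind == "fossil"
            and self.parent is not None
            and self.parent.age == self.age
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label or self.kind}, age={self.age:.3g})"


class SampledTree:
    """A sampled-ancestor time-tree with an origin time above the root."""

    def __init__(self, root: Node | None, origin_T: float) -> None:
        self.root = root
        self.origin_T = origin_T

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        if self.root is None:
            return
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def extant_tips(self) -> list[Node]:
        return [n for n in self.tips() if n.kind == "extant"]

    def fossil_tips(self) -> list[Node]:
        return [n for n in self.tips() if n.kind == "fossil"]

    def sampled_ancestors(self) -> list[Node]:
        return [n for n in self.fossil_tips() if n.is_sampled_ancestor]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    @property
    def n_extant(self) -> int:
        return len(self.extant_tips())

    @property
    def n_fossils(self) -> int:
        return len(self.fossil_tips())

    # -- validation --------------------------------------------------------

    def validate(self, atol: float = 1e-9) -> None:
        """Check the time-tree invariants; raise ValueError on violation."""
        if self.root is None:
            return
        if self.root.age > self.origin_T + atol:
            raise ValueError(
                f"root age {self.root.age} exceeds origin_T {self.origin_T}"
            )
        for node in self.postorder():
            if node.is_tip:
                if node.kind == "extant" and abs(node.age) > atol:
                    raise ValueError(f"extant tip {node.label} has age {node.age}")
                if node.kind == "fossil" and not (
                    0.0 < node.age < self.origin_T + atol
                ):
                    raise ValueError(
                        f"fossil tip {node.label} age {node.age} outside "
                        f"(0, {self.origin_T})"
                    )
            for child in node.children:
                if node.age < child.age - atol:
                    raise ValueError(
                        f"parent age {node.age} below child age {child.age}"
                    )
                if node.age - child.age < atol and not (
                    child.kind == "fossil" and child.is_tip
                ):
                    raise ValueError("zero-length branch to a non-fossil node")

    # -- copying -----------------------------------------------------------

    def copy(self) -> "SampledTree":
        mapping: dict[int, Node] = {}

        def clone(node: Node) -> Node:
            new = Node(node.age, node.kind, node.label)
            mapping[id(node)] = new
            for child in node.children:
                new.add_child(clone(child))
            return new

        return SampledTree(
            clone(self.root) if self.root is not None else None, self.origin_T
        )

    # -- Newick ------------------------------------------------------------

    def newick(self, precision: int = 12) -> str:
        """Newick string with branch lengths; sampled ancestors appear as
        zero-length terminal branches."""
        if self.root is None:
            return ";"

        def fmt(node: Node) -> str:
            blen = (
                (node.parent.age - node.age) if node.parent is not None else 0.0
            )
            blen = max(blen, 0.0)
            if node.is_tip:
                return f"{node.label}:{blen:.{precision}g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.label or ""
            return f"({inner}){label}:{blen:.{precision}g}"

        return fmt(self.root) + ";"

    # -- array encoding for the likelihood and tree-prior kernels ----------

    def to_arrays(self) -> "TreeArrays":
        nodes = list(self.postorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        parent = np.full(n, -1, dtype=np.int64)
        ages = np.empty(n, dtype=np.float64)
        is_tip = np.zeros(n, dtype=np.bool_)
        labels: list[str | None] = []
        for i, node in enumerate(nodes):
            ages[i] = node.age
            labels.append(node.label)
            if node.is_tip:
                is_tip[i] = True
            else:
                if len(node.children) != 2:
                    raise ValueError("tree must be binary for array encoding")
                left[i] = index[id(node.children[0])]
                right[i] = index[id(node.children[1])]
            if node.parent is not None:
                parent[i] = index[id(node.parent)]
        return TreeArrays(
            nodes=nodes,
            left=left,
            right=right,
            parent=parent,
            ages=ages,
            is_tip=is_tip,
            labels=labels,
            origin_T=self.origin_T,
        )


class TreeArrays:
    """Postorder array view of a :class:`SampledTree` (root is last)."""

    def __init__(self, nodes, left, right, parent, ages, is_tip, labels, origin_T):
        self.nodes = nodes
        self.left = left
        self.right = right
        self.parent = parent
        self.ages = ages
        self.is_tip = is_tip
        self.labels = labels
        self.origin_T = origin_T

    def durations(self) -> np.ndarray:
        """Branch duration above each node (origin branch for the root)."""
        dur = np.empty_like(self.ages)
        for i in range(len(self.ages)):
            p = self.parent[i]
            top = self.origin_T if p < 0 else self.ages[p]
            dur[i] = max(top - self.ages[i], 0.0)
        return dur
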