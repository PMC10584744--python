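"""Phylogenetic tree container and topology operations.

A light rooted node/edge structure backs both rooted and unrooted trees:
an unrooted binary tree is stored with a trifurcating root, and every
likelihood computed here uses reversible models, so root placement does not
affect results.  Splits (bipartitions) are canonicalized as the frozenset
of leaf labels on the side *not* containing the lexicographically smallest
leaf, which makes split sets comparable across arbitrary rootings.
"""

from __future__ import annotations

import io

import dendropy


class Node:
    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.label = label
        self.support: dict[str, float] | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted representation of a (possibly unrooted) phylogeny."""

    def __init__(self, root: Node):
        self.root = root

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)

        def build(dn) -> Node:
            node = Node(label=dn.taxon.label if dn.taxon else dn.label,
                        length=dn.edge.length if dn.edge.length is not None else 0.0)
            for ch in dn.child_nodes():
                node.add(build(ch))
            return node

        return cls(build(dt.seed_node))

    def to_newick(self, lengths: bool = True, support_key: str | None = None,
                  digits: int = 6) -> str:
        buf = io.StringIO()

        def fmt(label: str) -> str:
            if any(c in label for c in " ()[]:;,'"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def write(node: Node) -> None:
            if node.children:
                buf.write("(")
                for i, ch in enumerate(node.children):
                    if i:
                        buf.write(",")
                    write(ch)
                buf.write(")")
                if support_key and node.support and support_key in node.support:
                    buf.write(f"{node.support[support_key]:g}")
                elif node.label:
                    buf.write(fmt(node.label))
            else:
                buf.write(fmt(node.label) if node.label else "")
            if lengths and node.parent is not None:
                buf.write(f":{node.length:.{digits}g}")

        write(self.root)
        buf.write(";")
        return buf.getvalue()

    # --------------------------------------------------------- traversal
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for ch in node.children:
                    stack.append((ch, False))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> set[str]:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")
        return set(labels)

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = dict(node.support) if node.support else None
            for ch in node.children:
                new.add(dup(ch))
            return new
        return Tree(dup(self.root))

    # ------------------------------------------------------------ splits
    def _leafset_below(self) -> dict[int, frozenset[str]]:
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(ch)] for ch in node.children))
        return below

    def bipartitions(self, nontrivial_only: bool = True):
        """Canonical splits keyed by the child node defining each edge."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        n = len(all_leaves)
        below = self._leafset_below()
        out: dict[frozenset[str], Node] = {}
        for node in self.postorder():
            if node.parent is None:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            k = len(side)
            if nontrivial_only and not (2 <= k <= n - 2):
                continue
            if 1 <= len(side) <= n - 1:
                out[side] = node
        return out

    # ---------------------------------------------------------- rooting
    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a trifurcation (in place).

        The two root edges merge into one; a two-leaf tree is left as is.
        """
        r = self.root
        if len(r.children) == 2:
            a, b = r.children
            promote = a if not a.is_leaf else b
            if promote.is_leaf:
                return self
            other = b if promote is a else a
            other.length += promote.length
            r.children = list(promote.children) + [other]
            for c in r.children:
                c.parent = r
        return self

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the edge above ``child``."""
        tree = self.copy()
        # find the matching node in the copy by path from root
        path: list[int] = []
        node = child
        while node.parent is not None:
            path.append(node.parent.children.index(node))
            node = node.parent
        node = tree.root
        for idx in reversed(path):
            node = node.children[idx]
        child = node

        old_parent = child.parent
        if old_parent is None:
            return tree
        new_root = Node()
        upper = child.length * (1.0 - fraction)
        lower = child.length * fraction
        old_parent.children.remove(child)
        # flip parent pointers from old_parent up to the old root
        prev, prev_len = new_root, upper
        node = old_parent
        while node is not None:
            nxt, nxt_len = node.parent, node.length
            node.parent = prev
            node.length = prev_len
            if node not in prev.children:
                prev.children.append(node)
            if nxt is not None:
                nxt.children.remove(node)
            prev, prev_len = node, nxt_len
            node = nxt
        child.parent = new_root
        child.length = lower
        new_root.children.insert(0, child)
        # remove the degree-2 passthrough left at the old root position
        _suppress_unifurcations(new_root)
        return Tree(new_root)


def _suppress_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in list(node.children):
            stack.append(ch)
        if node.parent is not None and len(node.children) == 1:
            only = node.children[0]
            only.length += node.length
            only.parent = node.parent
            i = node.parent.children.index(node)
            node.parent.children[i] = only
        elif node.parent is None and len(node.children) == 1:
            # rootward unifurcation: lift grandchildren
            only = node.children[0]
            node.children = only.children
            for c in node.children:
                c.parent = node


def internal_edges(tree: Tree) -> list[Node]:
    """Child nodes defining internal (non-pendant) edges of the unrooted tree."""
    out = []
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        out.append(node)
    return out


def nni_neighbors(tree: Tree, edge_child: Node) -> list[Tree]:
    """The two nearest-neighbor-interchange rearrangements around an edge.

    ``edge_child`` must be an internal non-root node of ``tree`` (the edge is
    the one to its parent).  Returns new trees; the input is untouched.
    """
    if edge_child.is_leaf or edge_child.parent is None:
        raise ValueError("NNI edge must be internal")
    # locate edge_child in copies by positional path
    path: list[int] = []
    node = edge_child
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    path.reverse()

    out = []
    for which in (0, 1):
        t = tree.copy()
        v = t.root
        for idx in path:
            v = v.children[idx]
        u = v.parent
        # sibling subtree: another child of u, or (if u binary non-root) u's
        # parent-side is equivalent to the remaining sibling under unrooted NNI
        sibs = [c for c in u.children if c is not v]
        if not sibs:
            raise ValueError("degenerate edge for NNI")
        s = sibs[0]
        a = v.children[which]
        # swap subtree a with s
        ai, si = v.children.index(a), u.children.index(s)
        v.children[ai], u.children[si] = s, a
        s.parent, a.parent = v, u
        out.append(t)
    return out


def root_with_outgroup(tree: Tree, outgroup: set[str]) -> Tree:
    """Root on the branch subtending the outgroup.

    A single-leaf outgroup roots at the midpoint of its pendant branch; a
    multi-leaf outgroup must form a clade in the unrooted tree (its leaf set
    must be one side of some split), otherwise an error lists the leaves.
    """
    labels = tree.leaf_labels()
    outgroup = set(outgroup)
    if not outgroup <= labels:
        raise ValueError(f"outgroup leaves missing from tree: {sorted(outgroup - labels)}")
    if len(outgroup) == 1:
        target = next(n for n in tree.leaves() if n.label in outgroup)
        return tree.reroot_on_edge(target, fraction=0.5)
    og = frozenset(outgroup)
    below = tree._leafset_below()
    for node in tree.postorder():
        if node.parent is None:
            continue
        side = below[id(node)]
        if side == og or (labels - side) == og:
            if side == og:
                return tree.reroot_on_edge(node, fraction=0.5)
            return tree.reroot_on_edge(node, fraction=0.5)
    raise ValueError(f"outgroup not monophyletic in the unrooted tree: {sorted(outgroup)}")
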