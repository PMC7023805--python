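"""Rooted species tree with stable node identifiers.

The reconstruction machinery needs a rooted, (after preprocessing) strictly
bifurcating tree whose internal nodes carry stable, deterministic ids so
that per-node results are reproducible across runs and input orderings.
Children are therefore kept in canonical order (sorted by the smallest leaf
label in their subtree) and internal ids are assigned in preorder.  Leaves
are identified by their species label.

Newick parsing and writing is delegated to dendropy; branch lengths are
accepted and ignored (the method counts events per node, not per unit
time).
"""
from __future__ import annotations

import logging
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


class TreeNode:
    __slots__ = ("id", "label", "parent", "children")

    def __init__(self, label: Optional[str] = None) -> None:
        self.id: str = ""
        self.label = label
        self.parent: Optional["TreeNode"] = None
        self.children: List["TreeNode"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id or self.label!r})"


class PhyloTree:
    """Rooted bifurcating tree over named leaves, plus a designated outgroup.

    Node ids: a leaf's id is its label; internal nodes get preorder ids
    ``N1, N2, ...`` (prefix adjusted if a leaf label would collide).
    """

    def __init__(self, root: TreeNode, outgroup_leaves: Iterable[str] = ()) -> None:
        self._root = root
        self._canonicalize(root)
        self._validate_shape(root)
        self._assign_ids()
        og = frozenset(outgroup_leaves)
        unknown = og - self.leaf_labels
        if unknown:
            raise ValidationError(
                f"outgroup names not among leaves: {', '.join(sorted(unknown))}"
            )
        self.outgroup_leaves: FrozenSet[str] = og
        self._subtree_leaves: Dict[str, FrozenSet[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                self._subtree_leaves[node.id] = frozenset([node.label])
            else:
                acc = frozenset()
                for c in node.children:
                    acc |= self._subtree_leaves[c.id]
                self._subtree_leaves[node.id] = acc

    # -- construction -------------------------------------------------

    @staticmethod
    def _canonicalize(root: TreeNode) -> None:
        def min_leaf(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label or ""
            return min(min_leaf(c) for c in node.children)

        def sort_rec(node: TreeNode) -> None:
            node.children.sort(key=min_leaf)
            for c in node.children:
                c.parent = node
                sort_rec(c)

        root.parent = None
        sort_rec(root)

    def _validate_shape(self, root: TreeNode) -> None:
        labels: List[str] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                if not node.label:
                    raise ValidationError("every leaf must be named")
                labels.append(node.label)
            else:
                if len(node.children) != 2:
                    where = node.label or "/".join(sorted(
                        leaf.label for leaf in _iter_leaves(node)))
                    raise ValidationError(
                        f"tree is not bifurcating: node ({where}) has "
                        f"{len(node.children)} children"
                    )
                stack.extend(node.children)
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValidationError(f"duplicate leaf names: {', '.join(sorted(dupes))}")
        if len(labels) < 2:
            raise ValidationError("tree must have at least two leaves")

    def _assign_ids(self) -> None:
        leaf_labels = {n.label for n in _iter_leaves(self._root)}
        prefix = "N"
        while any(lbl.startswith(prefix) and lbl[len(prefix):].isdigit()
                  for lbl in leaf_labels):
            prefix = "_" + prefix
        counter = 0
        order: List[TreeNode] = []
        stack = [self._root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(node.children))
        for node in order:
            if node.is_leaf:
                node.id = node.label  # type: ignore[assignment]
            else:
                counter += 1
                node.id = f"{prefix}{counter}"
        self._preorder: Tuple[TreeNode, ...] = tuple(order)
        self._by_id: Dict[str, TreeNode] = {n.id: n for n in order}

    # -- basic queries -------------------------------------------------

    @property
    def root(self) -> TreeNode:
        return self._root

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise ValidationError(f"unknown node id {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._by_id

    def preorder(self) -> Sequence[TreeNode]:
        return self._preorder

    def postorder(self) -> List[TreeNode]:
        return list(reversed(self._preorder))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self._preorder if n.is_leaf]

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(n.label for n in _iter_leaves(self._root))

    @property
    def n_nodes(self) -> int:
        return len(self._preorder)

    def subtree_leaves(self, node_id: str) -> FrozenSet[str]:
        return self._subtree_leaves[node_id]

    # -- transformations ----------------------------------------------

    def prune(self, remove_labels: Iterable[str]) -> "PhyloTree":
        """Return a new tree without the given leaves.

        Internal nodes left with a single child are suppressed; if the root
        is left with one child, that child becomes the new root.  Outgroup
        designation is carried over (minus removed leaves).
        """
        remove = frozenset(remove_labels)
        unknown = remove - self.leaf_labels
        if unknown:
            raise ValidationError(
                f"cannot prune unknown leaves: {', '.join(sorted(unknown))}"
            )
        if len(self.leaf_labels - remove) < 2:
            raise ValidationError("pruning would leave fewer than two leaves")

        def build(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.label in remove:
                    return None
                return TreeNode(node.label)
            kids = [k for k in (build(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:  # suppress degree-2 node
                return kids[0]
            new = TreeNode()
            new.children = kids
            return new

        new_root = build(self._root)
        assert new_root is not None
        return PhyloTree(new_root, self.outgroup_leaves - remove)

    # -- newick io -----------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        text: str,
        outgroup: Iterable[str] = (),
        resolve_root: bool = False,
    ) -> "PhyloTree":
        """Parse a rooted Newick tree with named leaves.

        Multifurcations are rejected, except at the root when
        ``resolve_root`` is true and the designated outgroup allows
        grouping the remaining children into a single ingroup clade.
        Branch lengths are ignored.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            if "Multiple occurrences of the same taxa" in str(exc):
                raise ValidationError(f"duplicate leaf names in tree: {exc}") from exc
            raise FormatError(f"could not parse Newick tree: {exc}") from exc

        def convert(dnode) -> TreeNode:
            if not dnode.child_nodes():
                label = None
                if dnode.taxon is not None:
                    label = dnode.taxon.label
                elif dnode.label:
                    label = dnode.label
                if label is None:
                    raise ValidationError("every leaf must be named")
                return TreeNode(label.replace(" ", "_"))
            node = TreeNode()
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        root = convert(dtree.seed_node)
        og = frozenset(outgroup)
        if len(root.children) > 2 and resolve_root and og:
            root = _resolve_root_multifurcation(root, og)
        return cls(root, og)

    @classmethod
    def from_nested(
        cls, nested, outgroup: Iterable[str] = ()
    ) -> "PhyloTree":
        """Build a tree from nested tuples of leaf labels, e.g.
        ``(("A", "B"), ("C", "D"))``."""

        def build(item) -> TreeNode:
            if isinstance(item, str):
                return TreeNode(item)
            node = TreeNode()
            node.children = [build(sub) for sub in item]
            return node

        return cls(build(nested), outgroup)

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label  # type: ignore[return-value]
            return "(" + ",".join(render(c) for c in node.children) + ")"

        return render(self._root) + ";"


def _iter_leaves(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _resolve_root_multifurcation(root: TreeNode, outgroup: FrozenSet[str]) -> TreeNode:
    """Group a multifurcating root's children into outgroup vs ingroup."""

    def leafset(node: TreeNode) -> FrozenSet[str]:
        return frozenset(leaf.label for leaf in _iter_leaves(node))

    og_children = [c for c in root.children if leafset(c) <= outgroup]
    in_children = [c for c in root.children if not (leafset(c) <= outgroup)]
    if not og_children or not in_children:
        raise ValidationError(
            "cannot resolve root multifurcation: outgroup does not split the root children"
        )

    def join(children: List[TreeNode]) -> TreeNode:
        if len(children) == 1:
            return children[0]
        if len(children) == 2:
            node = TreeNode()
            node.children = children
            return node
        raise ValidationError(
            "cannot resolve root multifurcation into a bifurcating tree"
        )

    new_root = TreeNode()
    new_root.children = [join(og_children), join(in_children)]
    logger.info("resolved root multifurcation using the outgroup designation")
    return new_root
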