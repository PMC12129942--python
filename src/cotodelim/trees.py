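"""Support-annotated phylogenetic trees.

Trees enter the pipeline as Newick text whose internal-node labels carry
branch support, either as a dual ``"SH-aLRT/UFboot"`` pair (the IQ-TREE
convention, e.g. ``99.8/100``) or as a single bootstrap percentage. The
:class:`SupportTree` wrapper keeps the two support slots per internal
edge and exposes the bipartition view used by all clade logic, so root
placement never matters.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

DUAL_SLASH = "dual_slash"
SINGLE = "single"


class TreeParseError(ValueError):
    """Malformed Newick or support label."""


def _fmt(x: float) -> str:
    return f"{x:g}"


class SupportTree:
    """A leaf-labelled tree whose internal edges carry (SH-aLRT, UFboot).

    Missing support is ``None`` and is distinct from a support of 0:
    threshold tests on absent support fail closed.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise TreeParseError("duplicate leaf labels")
        self._leaves = frozenset(labels)
        for node in tree.preorder_node_iter():
            if not hasattr(node, "sh_alrt"):
                node.sh_alrt = None
            if not hasattr(node, "ufboot"):
                node.ufboot = None

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, label_style: str = DUAL_SLASH
                    ) -> "SupportTree":
        return parse_support_tree(text, label_style)

    # -- views -------------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset:
        return self._leaves

    def _leafset_below(self, node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def bipartition_sides(self) -> dict[frozenset, object]:
        """Map each non-root node's below-edge leaf set to that node.

        Every internal edge of the unrooted tree is represented by at
        least one side; the complementary side may or may not appear as
        a key (it does for children of a bifurcating root).
        """
        sides: dict[frozenset, object] = {}
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            sides.setdefault(self._leafset_below(node), node)
        return sides

    def internal_sides(self) -> dict[frozenset, object]:
        """Bipartition sides with >= 2 leaves on the below side."""
        return {s: n for s, n in self.bipartition_sides().items()
                if len(s) >= 2}

    def support_of_side(self, side: frozenset) -> tuple:
        """Supports (sh_alrt, ufboot) of the edge defining ``side``.

        ``side`` may be given as either half of the bipartition.
        Returns ``(None, None)`` when the edge is unlabelled and raises
        ``KeyError`` when no edge induces the bipartition.
        """
        sides = self.bipartition_sides()
        node = sides.get(frozenset(side))
        if node is None:
            node = sides.get(self._leaves - frozenset(side))
        if node is None:
            raise KeyError("no edge induces the requested bipartition")
        return (node.sh_alrt, node.ufboot)

    # -- serialization -----------------------------------------------

    def to_newick(self, label_style: str = DUAL_SLASH) -> str:
        tree = self.tree
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.sh_alrt is None and node.ufboot is None:
                node.label = None
            elif label_style == DUAL_SLASH:
                sh = "" if node.sh_alrt is None else _fmt(node.sh_alrt)
                uf = "" if node.ufboot is None else _fmt(node.ufboot)
                node.label = f"{sh}/{uf}"
            else:
                v = node.ufboot if node.ufboot is not None else node.sh_alrt
                node.label = _fmt(v)
        return tree.as_string(schema="newick",
                              suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<SupportTree {len(self._leaves)} leaves>"


def _parse_label(label: str, label_style: str, node_name: str
                 ) -> tuple:
    if label_style == DUAL_SLASH:
        parts = label.split("/")
        if len(parts) != 2:
            raise TreeParseError(
                f"support label {label!r} at node above {node_name!r} is "
                f"not of the form 'SH-aLRT/UFboot'")
        try:
            sh = float(parts[0]) if parts[0] else None
            uf = float(parts[1]) if parts[1] else None
        except ValueError as exc:
            raise TreeParseError(
                f"non-numeric support label {label!r} at node above "
                f"{node_name!r}") from exc
        return sh, uf
    if label_style == SINGLE:
        try:
            v = float(label)
        except ValueError as exc:
            raise TreeParseError(
                f"non-numeric support label {label!r} at node above "
                f"{node_name!r}") from exc
        # a single bootstrap value fills both slots
        return v, v
    raise ValueError(f"unknown label style {label_style!r}")


def parse_support_tree(newick_text: str, label_style: str = DUAL_SLASH
                       ) -> SupportTree:
    """Parse Newick text with support-bearing internal node labels.

    Unlabelled internal edges get absent (``None``) supports. Leaf
    labels are preserved verbatim.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True)
    except Exception as exc:
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise TreeParseError(f"malformed Newick{where}: {exc}") from exc
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        node.sh_alrt = None
        node.ufboot = None
        if node.is_leaf() or node is root:
            continue
        if node.label not in (None, ""):
            name = min(lf.taxon.label for lf in node.leaf_iter())
            node.sh_alrt, node.ufboot = _parse_label(
                str(node.label), label_style, name)
    return SupportTree(tree)


def build_tree(newick_topology: str,
               supports: dict[frozenset, tuple] | None = None
               ) -> SupportTree:
    """Build a SupportTree from plain Newick plus an explicit support map.

    ``supports`` maps a bipartition side (frozenset of leaf labels) to an
    (sh_alrt, ufboot) pair; convenient for programmatic fixtures.
    """
    st = parse_support_tree(newick_topology, DUAL_SLASH)
    if supports:
        sides = st.bipartition_sides()
        for side, (sh, uf) in supports.items():
            node = sides.get(frozenset(side))
            if node is None:
                node = sides.get(st.leaf_labels - frozenset(side))
            if node is None:
                raise KeyError(f"no edge induces side {sorted(side)}")
            node.sh_alrt, node.ufboot = sh, uf
    return st


def random_topology_newick(labels: Iterable[str], rng) -> str:
    """Random binary topology over ``labels`` by sequential random joins.

    ``rng`` is a ``random.Random``; returns plain Newick without supports.
    """
    items = [str(l) for l in labels]
    while len(items) > 1:
        i, j = sorted(rng.sample(range(len(items)), 2))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return items[0] + ";"
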