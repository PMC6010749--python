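"""Rooted tree topologies: parsing, comparison, combination, pruning.

The occurrence model consumes *topology only*: branch lengths carry an
evolutionary-distance interpretation the model deliberately avoids, so they
are discarded on input, as are internal node labels.  Nodes are numbered in
preorder starting at 1 (the root), so every child id is strictly greater
than its parent id; this numbering is what the slope cascade in
:mod:`phylobeta.model` indexes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "Node",
    "Topology",
    "TreeError",
    "TreeParseError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "robinson_foulds",
    "build_supertree",
    "prune_leaves",
]

ROOT_PARENT = 0  # parent-id sentinel carried by the root node

Split = tuple[str, ...]  # canonical bipartition side, sorted labels


class TreeError(ValueError):
    """Invalid tree structure or incompatible tree operands."""


class TreeParseError(TreeError):
    """Malformed Newick input."""


@dataclass(frozen=True)
class Node:
    id: int
    parent_id: int  # ROOT_PARENT for the root
    label: str  # leaf taxon name; "" for internal nodes


class Topology:
    """A rooted tree over labelled leaves, preorder-numbered from 1.

    Invariants (checked on construction): exactly one root with id 1;
    ``parent_id < id`` for every non-root node; leaf labels unique and
    non-empty; internal labels empty.  Polytomies and unary chains are
    permitted.
    """

    def __init__(self, nodes: Sequence[Node]):
        nodes = tuple(nodes)
        if not nodes:
            raise TreeError("a topology needs at least one node")
        ids = [n.id for n in nodes]
        if ids != list(range(1, len(nodes) + 1)):
            raise TreeError("node ids must be 1..n in order")
        if nodes[0].parent_id != ROOT_PARENT:
            raise TreeError("node 1 must be the root")
        for n in nodes[1:]:
            if not (ROOT_PARENT < n.parent_id < n.id):
                raise TreeError(
                    f"node {n.id}: parent id {n.parent_id} violates preorder"
                )
        self.nodes = nodes
        self._children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for n in nodes[1:]:
            self._children[n.parent_id].append(n.id)
        labels = [n.label for n in nodes if self.is_leaf(n.id)]
        if any(not lb for lb in labels):
            raise TreeError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dups = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeError(f"duplicate leaf labels: {dups}")
        for n in nodes:
            if not self.is_leaf(n.id) and n.label:
                raise TreeError(f"internal node {n.id} must be unlabelled")

    # -- basic accessors -------------------------------------------------

    @property
    def root_id(self) -> int:
        return 1

    def is_leaf(self, node_id: int) -> bool:
        return not self._children[node_id]

    def children(self, node_id: int) -> tuple[int, ...]:
        return tuple(self._children[node_id])

    def parent(self, node_id: int) -> int:
        """Parent id, or ROOT_PARENT for the root."""
        return self.nodes[node_id - 1].parent_id

    def label(self, node_id: int) -> str:
        return self.nodes[node_id - 1].label

    @property
    def node_ids(self) -> range:
        return range(1, len(self.nodes) + 1)

    @property
    def leaf_ids(self) -> tuple[int, ...]:
        return tuple(i for i in self.node_ids if self.is_leaf(i))

    @property
    def internal_ids(self) -> tuple[int, ...]:
        return tuple(i for i in self.node_ids if not self.is_leaf(i))

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(self.label(i) for i in self.leaf_ids)

    @property
    def leaf_count(self) -> int:
        return len(self.leaf_ids)

    def leaf_set_below(self, node_id: int) -> frozenset[str]:
        """Labels of all leaves in the clade rooted at ``node_id``."""
        out: list[str] = []
        stack = [node_id]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(self.label(v))
            else:
                stack.extend(self._children[v])
        return frozenset(out)

    def ancestors(self, node_id: int) -> Iterable[int]:
        """Yield parent, grandparent, ... up to and including the root."""
        v = self.parent(node_id)
        while v != ROOT_PARENT:
            yield v
            v = self.parent(v)

    # -- identity --------------------------------------------------------

    def _canonical(self, node_id: int = 1):
        if self.is_leaf(node_id):
            return self.label(node_id)
        return tuple(
            sorted(
                (self._canonical(c) for c in self._children[node_id]),
                key=lambda s: s if isinstance(s, str) else str(s),
            )
        )

    def __eq__(self, other: object) -> bool:
        """Equality of the rooted shape, ignoring child order."""
        if not isinstance(other, Topology):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Topology({write_newick(self)!r})"


# -- Newick I/O ----------------------------------------------------------


def parse_newick(text: str) -> Topology:
    """Parse one rooted Newick tree, discarding branch lengths and
    internal labels.

    Quoted labels and square-bracket comments are accepted; duplicate leaf
    labels raise :class:`TreeError`; malformed input raises
    :class:`TreeParseError` naming the offending position.
    """
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    nodes: list[Node] = []
    counter = itertools.count(1)
    ids: dict[object, int] = {}

    for dnode in dtree.preorder_node_iter():
        nid = next(counter)
        ids[dnode] = nid
        parent = ids[dnode.parent_node] if dnode.parent_node is not None else ROOT_PARENT
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else ""
            if not label:
                raise TreeError("unlabelled leaf in Newick input")
        else:
            label = ""
        nodes.append(Node(id=nid, parent_id=parent, label=label))
    return Topology(nodes)


def _check_balanced(text: str) -> None:
    """Pre-scan for unbalanced parentheses/quotes, reporting the position."""
    depth = 0
    in_quote = False
    for pos, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise TreeParseError(
                        f"unbalanced ')' at character {pos}"
                    )
    if in_quote:
        raise TreeParseError("unterminated quote in Newick input")
    if depth != 0:
        raise TreeParseError(
            f"{depth} unclosed '(' by character {len(text)}"
        )


def _quote(label: str) -> str:
    if label and all(c.isalnum() or c in "_.-" for c in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(t: Topology) -> str:
    """Serialize a topology as Newick (no branch lengths)."""

    def render(node_id: int) -> str:
        if t.is_leaf(node_id):
            return _quote(t.label(node_id))
        inner = ",".join(render(c) for c in t.children(node_id))
        return f"({inner})"

    return render(t.root_id) + ";"


# -- bipartitions and Robinson-Foulds ------------------------------------


def _canonical_split(side: frozenset[str], all_leaves: frozenset[str]) -> Split:
    a = tuple(sorted(side))
    b = tuple(sorted(all_leaves - side))
    return min(a, b)


def bipartitions(t: Topology) -> frozenset[Split]:
    """Non-trivial unrooted splits of ``t``, one per internal edge.

    Each split is reported as the lexicographically smaller side, sorted,
    so membership is independent of rooting and child order.  The two root
    edges of a bifurcating root induce the same split and are counted once.
    """
    full = frozenset(t.leaf_labels)
    out: set[Split] = set()
    for v in t.internal_ids:
        if v == t.root_id:
            continue
        clade = t.leaf_set_below(v)
        if len(clade) < 2 or len(full - clade) < 2:
            continue
        out.add(_canonical_split(clade, full))
    return frozenset(out)


def robinson_foulds(t1: Topology, t2: Topology) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial split sets.  Requires identical leaf sets."""
    l1, l2 = set(t1.leaf_labels), set(t2.leaf_labels)
    if l1 != l2:
        raise TreeError(
            f"leaf sets differ; symmetric difference: {sorted(l1 ^ l2)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


# -- supertree -----------------------------------------------------------


def build_supertree(trees: Sequence[Topology]) -> Topology:
    """Combine source topologies into one rooted supertree over the union
    of their leaves.

    Greedy clade heuristic: every clade of every input is a candidate; a
    candidate's support is the fraction of *informative* trees (those
    whose leaf set could display a non-trivial projection of it) that do
    display it.  Candidates are ranked by (support, then smaller size,
    then lexical order of the sorted label tuple) and accepted in that
    order when (a) supported by at least half of their informative trees
    and (b) laminar with the clades already accepted; the tree is read
    off the accepted family.  Inputs that agree are reproduced exactly;
    conflicts resolve toward the better-supported clade and never fail —
    unresolvable structure is left as a polytomy.  The majority filter
    makes the result a Robinson-Foulds median of inputs sharing one leaf
    set: its total RF distance to the inputs never exceeds that of any
    single input used as-is.
    """
    if not trees:
        raise TreeError("need at least one input tree")
    union: set[str] = set()
    for t in trees:
        union.update(t.leaf_labels)
    full = frozenset(union)

    tree_leafsets = [frozenset(t.leaf_labels) for t in trees]
    tree_clades: list[set[frozenset[str]]] = []
    candidates: set[frozenset[str]] = set()
    for t in trees:
        clades = {
            t.leaf_set_below(v)
            for v in t.internal_ids
        }
        clades = {c for c in clades if len(c) >= 2}
        tree_clades.append(clades)
        candidates.update(c for c in clades if c != full)

    def support(clade: frozenset[str]) -> tuple[int, int]:
        displayed = informative = 0
        for leaves, clades in zip(tree_leafsets, tree_clades):
            proj = clade & leaves
            if len(proj) < 2 or not (leaves - clade):
                continue  # this tree cannot display the clade non-trivially
            informative += 1
            if proj in clades:
                displayed += 1
        return displayed, informative

    scored = {c: support(c) for c in candidates}

    def rank(clade: frozenset[str]):
        disp, info = scored[clade]
        freq = disp / info if info else 1.0
        return (-freq, len(clade), tuple(sorted(clade)))

    accepted: list[frozenset[str]] = []
    for clade in sorted(candidates, key=rank):
        disp, info = scored[clade]
        if 2 * disp < info:
            continue  # minority clade: would worsen total RF distance
        if all(
            not (clade & c) or clade <= c or c <= clade for c in accepted
        ):
            accepted.append(clade)

    return _tree_from_laminar_clades(full, accepted)


def _tree_from_laminar_clades(
    full: frozenset[str], clades: Sequence[frozenset[str]]
) -> Topology:
    """Build the rooted topology whose internal nodes are ``full`` plus the
    given laminar family of proper sub-clades."""
    ordered = sorted(set(clades), key=lambda c: (-len(c), tuple(sorted(c))))
    parent_of: dict[frozenset[str] | str, frozenset[str]] = {}
    for i, c in enumerate(ordered):
        holder = full
        for d in ordered[:i]:  # larger clades first: last superset is smallest
            if c < d:
                holder = d
        parent_of[c] = holder
    for leaf in sorted(full):
        holder = full
        for d in ordered:
            if leaf in d:
                holder = d  # ordered by decreasing size: ends at smallest
        parent_of[leaf] = holder

    children: dict[frozenset[str], list] = {full: []}
    for c in ordered:
        children[c] = []
    for child, par in parent_of.items():
        children[par].append(child)

    def sort_key(item):
        return tuple(sorted(item)) if isinstance(item, frozenset) else (item,)

    nodes: list[Node] = []
    counter = itertools.count(1)

    def emit(item, parent_id: int) -> None:
        nid = next(counter)
        if isinstance(item, frozenset):
            nodes.append(Node(id=nid, parent_id=parent_id, label=""))
            for ch in sorted(children[item], key=sort_key):
                emit(ch, nid)
        else:
            nodes.append(Node(id=nid, parent_id=parent_id, label=item))

    emit(full, ROOT_PARENT)
    return Topology(nodes)


# -- pruning -------------------------------------------------------------

SUPPRESSED = None  # prune map value for nodes removed or smoothed away


def prune_leaves(
    t: Topology, drop: Iterable[str]
) -> tuple[Topology, Mapping[int, int | None]]:
    """Remove the named leaves and suppress resulting unary internal nodes.

    Returns the pruned topology (preorder ids recomputed) and a map from
    old node id to new node id, with ``None`` for nodes that were removed
    or suppressed.  Dropping nothing returns an identical topology with the
    identity map.
    """
    drop = set(drop)
    labels = set(t.leaf_labels)
    unknown = drop - labels
    if unknown:
        raise TreeError(f"cannot drop unknown leaves: {sorted(unknown)}")
    if drop == labels:
        raise TreeError("cannot drop every leaf")

    # survives[v]: v is a kept leaf or has a surviving descendant leaf
    survives: dict[int, bool] = {}
    for v in reversed(t.node_ids):
        if t.is_leaf(v):
            survives[v] = t.label(v) not in drop
        else:
            survives[v] = any(survives[c] for c in t.children(v))

    def surviving_children(v: int) -> list[int]:
        return [c for c in t.children(v) if survives[c]]

    # walk past unary chains starting at the old root
    new_root = t.root_id
    while not t.is_leaf(new_root) and len(surviving_children(new_root)) == 1:
        new_root = surviving_children(new_root)[0]

    mapping: dict[int, int | None] = {v: SUPPRESSED for v in t.node_ids}
    nodes: list[Node] = []
    counter = itertools.count(1)

    def emit(old_id: int, new_parent: int) -> None:
        kids = surviving_children(old_id)
        if not t.is_leaf(old_id) and len(kids) == 1 and old_id != new_root:
            emit(kids[0], new_parent)  # unary: smooth this node away
            return
        nid = next(counter)
        mapping[old_id] = nid
        nodes.append(Node(id=nid, parent_id=new_parent, label=t.label(old_id)))
        for c in kids:
            emit(c, nid)

    emit(new_root, ROOT_PARENT)
    return Topology(nodes), mapping
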