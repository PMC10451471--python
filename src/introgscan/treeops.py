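"""Tree parsing and topology classification.

Trees are handled as :class:`dendropy.Tree` objects with unrooted
semantics: every classification below is phrased in terms of the
bipartitions (splits) a tree contains, so the placement of the root in
the input newick never changes the result.

Two classifiers are provided:

* :func:`classify_quartet_topology` — resolve the induced topology of a
  rooted quartet ``(((P1,P2),P3),O)`` inside an arbitrary gene tree;
  this feeds the gene-tree Delta statistic.
* :func:`classify_tree_for_branch` — classify a gene tree against one
  internal species-tree branch and the two alternative resolutions of
  that branch produced by nearest-neighbor interchange (NNI); this
  feeds gene concordance factors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "QuartetSpec",
    "QuartetTopology",
    "BranchContext",
    "BranchClass",
    "read_trees",
    "write_trees",
    "leaf_labels",
    "restricted_bipartitions",
    "classify_quartet_topology",
    "classify_tree_for_branch",
    "branch_contexts",
]


class QuartetTopology(enum.Enum):
    """Induced unrooted topology of a quartet inside a gene tree."""

    CONCORDANT = "concordant"  # P1P2 | P3,O
    DISC1 = "disc1"            # P2P3 | P1,O
    DISC2 = "disc2"            # P1P3 | P2,O
    UNINFORMATIVE = "uninformative"


class BranchClass(enum.Enum):
    """Classification of a gene tree relative to a species-tree branch."""

    CONCORDANT = "concordant"
    DF1 = "df1"                # NNI joining A with C
    DF2 = "df2"                # NNI joining A with D
    PARAPHYLETIC = "paraphyletic"
    NONDECISIVE = "nondecisive"


@dataclass(frozen=True)
class QuartetSpec:
    """A rooted quartet ``(((p1,p2),p3),outgroup)``.

    ``disc1`` is the topology joining p2 with p3 (the pattern expected
    in excess when p2 and p3 exchanged genes), ``disc2`` joins p1 with
    p3 — mirroring the orientation convention of the D statistic.
    """

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(labels)) != 4:
            raise ValueError(f"quartet labels must be distinct: {labels}")

    @property
    def labels(self) -> frozenset:
        return frozenset((self.p1, self.p2, self.p3, self.outgroup))

    def swap_p1_p2(self) -> "QuartetSpec":
        return QuartetSpec(self.p2, self.p1, self.p3, self.outgroup)


@dataclass(frozen=True)
class BranchContext:
    """The four leaf sets flanking an internal species-tree branch.

    The branch separates A∪B from C∪D; A and B hang off one endpoint,
    C and D off the other. The two NNI rearrangements regroup the sets
    as (A∪C | B∪D) (df1) and (A∪D | B∪C) (df2).
    """

    branch_id: str
    a: frozenset
    b: frozenset
    c: frozenset
    d: frozenset

    def __post_init__(self) -> None:
        sets = [self.a, self.b, self.c, self.d]
        if any(not s for s in sets):
            raise ValueError("all four flanking leaf sets must be nonempty")
        union = self.a | self.b | self.c | self.d
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("flanking leaf sets must be disjoint")

    @property
    def all_leaves(self) -> frozenset:
        return self.a | self.b | self.c | self.d


def read_trees(source, rooted: bool = False) -> list[dendropy.Tree]:
    """Read newick trees from a path or string.

    Polytomous trees are accepted; each returned tree carries a boolean
    attribute ``has_polytomy``.
    """
    kwargs = {
        "schema": "newick",
        "rooting": "force-rooted" if rooted else "default-unrooted",
        "suppress_internal_node_taxa": True,
    }
    try:
        if hasattr(source, "read") or _looks_like_newick(str(source)):
            trees = dendropy.TreeList.get(data=_as_text(source), **kwargs)
        else:
            trees = dendropy.TreeList.get(path=str(source), **kwargs)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ValueError(f"malformed newick in {source!r}: {exc}") from exc
    out = list(trees)
    for t in out:
        t.has_polytomy = _has_polytomy(t)
    return out


def write_trees(trees: Iterable[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip())
            fh.write("\n")


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _looks_like_newick(s: str) -> bool:
    s = s.strip()
    return s.startswith("(") and s.endswith(";")


def _has_polytomy(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_node_iter():
        nch = len(node._child_nodes)
        if node.parent_node is None:
            # an unrooted tree read as a basal trifurcation is fine
            if nch > 3:
                return True
        elif nch > 2:
            return True
    return False


def restricted_bipartitions(
    tree: dendropy.Tree, labels: frozenset
) -> Iterator[frozenset]:
    """Yield, for every internal edge, the edge's child-side leaf set
    intersected with ``labels``. Duplicates and trivial restrictions
    (size 0, 1, or all of ``labels``) are not filtered here."""
    # single postorder pass accumulating restricted leaf sets
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[id(node)] = frozenset((lab,)) if lab in labels else frozenset()
        else:
            acc = frozenset()
            for ch in node._child_nodes:
                acc |= below[id(ch)]
            below[id(node)] = acc
            if node.parent_node is not None:
                yield acc


def _find_split(
    tree: dendropy.Tree, labels: frozenset, targets: dict
):
    """Return the value of the first target split found in the tree.

    ``targets`` maps frozenset (one side of a split of ``labels``) to an
    arbitrary value; a restricted bipartition matches a target if it
    equals the target side or its complement within ``labels``.
    """
    for side in restricted_bipartitions(tree, labels):
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        hit = targets.get(side)
        if hit is not None:
            return hit
        hit = targets.get(labels - side)
        if hit is not None:
            return hit
    return None


def classify_quartet_topology(
    tree: dendropy.Tree, q: QuartetSpec
) -> QuartetTopology:
    """Classify the induced topology of quartet ``q`` in ``tree``.

    The tree is restricted to the four labels; the classification is the
    unique nontrivial split of the restriction, or UNINFORMATIVE when a
    label is missing or the restriction is a star (polytomy).
    """
    labels = q.labels
    present = leaf_labels(tree)
    if not labels <= present:
        return QuartetTopology.UNINFORMATIVE
    targets = {
        frozenset((q.p1, q.p2)): QuartetTopology.CONCORDANT,
        frozenset((q.p2, q.p3)): QuartetTopology.DISC1,
        frozenset((q.p1, q.p3)): QuartetTopology.DISC2,
    }
    hit = _find_split(tree, labels, targets)
    return hit if hit is not None else QuartetTopology.UNINFORMATIVE


def classify_tree_for_branch(
    tree: dendropy.Tree, ctx: BranchContext
) -> BranchClass:
    """Classify a gene tree against one species-tree branch.

    A gene tree is *decisive* for the branch iff it contains at least
    one leaf from each of the four flanking sets. A decisive tree is
    concordant iff it contains a bipartition separating (A∪B) from
    (C∪D) on the shared taxa; df1/df2 likewise for the two NNI splits;
    otherwise (including polytomies at the relevant split) it counts as
    paraphyletic.
    """
    present = leaf_labels(tree)
    a = ctx.a & present
    b = ctx.b & present
    c = ctx.c & present
    d = ctx.d & present
    if not (a and b and c and d):
        return BranchClass.NONDECISIVE
    shared = a | b | c | d
    targets = {
        frozenset(a | b): BranchClass.CONCORDANT,
        frozenset(a | c): BranchClass.DF1,
        frozenset(a | d): BranchClass.DF2,
    }
    hit = _find_split(tree, shared, targets)
    return hit if hit is not None else BranchClass.PARAPHYLETIC


def branch_contexts(species_tree: dendropy.Tree) -> list[BranchContext]:
    """Enumerate the internal branches of a species tree with their four
    flanking leaf sets, under unrooted semantics.

    For a rooted binary input the two edges meeting at the root form a
    single unrooted branch and are reported once. Branch ids are
    assigned in preorder as ``b1, b2, ...``.
    """
    total = leaf_labels(species_tree)
    below: dict[int, frozenset] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset((node.taxon.label,))
        else:
            acc = frozenset()
            for ch in node._child_nodes:
                acc |= frozenset(below[id(ch)])
            below[id(node)] = acc

    root = species_tree.seed_node
    contexts: list[BranchContext] = []
    counter = 0
    root_children = list(root._child_nodes)
    root_is_bifurcation = len(root_children) == 2

    def child_leafsets(node) -> list[frozenset]:
        return [below[id(ch)] for ch in node._child_nodes]

    seen_root_edge = False
    for node in species_tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        parent = node.parent_node
        kids = child_leafsets(node)
        if len(kids) != 2:
            raise ValueError("species tree must be binary")
        a, b = kids
        if root_is_bifurcation and parent is root:
            # the root edge: other side is the sibling subtree
            if seen_root_edge:
                continue
            sib = next(ch for ch in root_children if ch is not node)
            if sib.is_leaf():
                continue  # pendant edge in the unrooted tree
            sib_kids = child_leafsets(sib)
            if len(sib_kids) != 2:
                raise ValueError("species tree must be binary")
            c, d = sib_kids
            seen_root_edge = True
        else:
            # other endpoint = parent; its flanks are the sibling subtree
            # and everything outside parent's clade
            sibs = [below[id(ch)] for ch in parent._child_nodes if ch is not node]
            rest = total - below[id(parent)]
            if parent is root and len(sibs) == 2:
                # unrooted basal trifurcation
                c, d = sibs
            elif len(sibs) == 1 and rest:
                c, d = sibs[0], rest
            else:
                raise ValueError("species tree must be binary")
        counter += 1
        contexts.append(
            BranchContext(f"b{counter}", frozenset(a), frozenset(b),
                          frozenset(c), frozenset(d))
        )
    return contexts
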