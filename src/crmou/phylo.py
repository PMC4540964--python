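"""Rooted phylogenies and branch-regime paintings.

All evolutionary models in this package live on a rooted tree with strictly
positive branch lengths (time, in arbitrary but consistent units).  A
*regime painting* labels every branch either ``base`` or ``shift``: the
``shift`` branches carry a distinct trait optimum in the Hansen model.
Shifted branches are derived from a set of tip labels; each maximal shifted
clade includes its stem branch, i.e. the optimum changes on the lineage
leading to the clade.

The ten built-in branch-shift scenarios (plus Brownian motion and the
single-optimum model M0) follow the classical 12-species *Drosophila*
phylogeny, with tip-name aliasing so that trees labelled ``Dmel``,
``dmel`` or ``D. melanogaster`` all resolve.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "NewickError",
    "PaintingError",
    "Node",
    "PhyloTree",
    "RegimePainting",
    "parse_newick",
    "paint_clade",
    "paint_tips",
    "bm_painting",
    "m0_painting",
    "builtin_regimes",
    "drosophila_tree",
    "BASE",
    "SHIFT",
    "DROSOPHILA_12",
    "BUILTIN_SHIFT_TIPS",
]

BASE = "base"
SHIFT = "shift"


class NewickError(ValueError):
    """Malformed newick input or violated tree invariants."""


class PaintingError(ValueError):
    """Invalid regime specification (unknown tips, broken monophyly...)."""


class Node:
    """A tree node; ``length`` is the branch above it (None for the root)."""

    __slots__ = ("label", "length", "children", "parent", "index", "time")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.index: int = -1
        self.time: float = 0.0

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label!r}, length={self.length})"


class PhyloTree:
    """Rooted tree with branch lengths.

    Invariants enforced at construction: exactly one root, unique tip
    labels, strictly positive branch length on every non-root node.
    """

    def __init__(self, root: Node):
        self.root = root
        self._preorder: list[Node] = []
        self._tip_map: dict[str, Node] = {}
        self._tipsets: dict[int, frozenset[str]] = {}
        self._finalize()

    # -- construction -------------------------------------------------

    def _finalize(self) -> None:
        order: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(node.children))
        self._preorder = order
        self.root.time = 0.0
        self.root.index = 0
        for i, node in enumerate(order):
            node.index = i
            if node is self.root:
                continue
            if node.length is None:
                raise NewickError(
                    f"missing branch length above node {node.label or '<internal>'}"
                )
            if not (node.length > 0):
                raise NewickError(
                    f"non-positive branch length ({node.length}) above node "
                    f"{node.label or '<internal>'}; all non-root branches must be "
                    "> 0 (add a small jitter to zero-length branches)"
                )
            node.time = node.parent.time + node.length
        tips = [n for n in order if n.is_tip]
        for tip in tips:
            if not tip.label:
                raise NewickError("unlabeled tip")
            if tip.label in self._tip_map:
                raise NewickError(f"duplicate tip label: {tip.label!r}")
            self._tip_map[tip.label] = tip

    # -- basic queries -------------------------------------------------

    @property
    def preorder(self) -> list[Node]:
        return self._preorder

    @property
    def tips(self) -> list[Node]:
        return [n for n in self._preorder if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self._tip_map)

    @property
    def height(self) -> float:
        return max(n.time for n in self.tips)

    def tip(self, label: str) -> Node:
        try:
            return self._tip_map[label]
        except KeyError:
            raise PaintingError(f"unknown tip: {label!r}") from None

    def tipset(self, node: Node) -> frozenset[str]:
        """Labels of all tips in the subtree rooted at ``node`` (cached)."""
        cached = self._tipsets.get(node.index)
        if cached is not None:
            return cached
        if node.is_tip:
            result = frozenset([node.label])
        else:
            result = frozenset().union(*(self.tipset(c) for c in node.children))
        self._tipsets[node.index] = result
        return result

    def mrca(self, labels: Iterable[str]) -> Node:
        want = frozenset(labels)
        missing = want - set(self._tip_map)
        if missing:
            raise PaintingError(f"unknown tips: {sorted(missing)}")
        if not want:
            raise PaintingError("empty tip set")
        node = self.root
        while True:
            for child in node.children:
                if want <= self.tipset(child):
                    node = child
                    break
            else:
                return node

    def branch_id(self, node: Node) -> str:
        """Stable identifier for the branch above ``node``."""
        if node is self.root:
            raise ValueError("the root has no branch")
        return node.label if node.is_tip else f"n{node.index}"

    def branch_ids(self) -> list[str]:
        return [self.branch_id(n) for n in self._preorder if n is not self.root]

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = _quote_label(node.label)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += _quote_label(node.label)
            if node.length is not None:
                core += f":{node.length:.10g}"
            return core

        return fmt(self.root) + ";"

    # -- editing -------------------------------------------------------

    def prune(self, keep: Iterable[str]) -> "PhyloTree":
        """Induced subtree on ``keep`` tips, unary nodes collapsed.

        Branch lengths along collapsed paths are summed, so root-to-tip
        distances among kept tips are preserved.
        """
        keep = frozenset(keep)
        missing = keep - set(self._tip_map)
        if missing:
            raise PaintingError(f"unknown tips: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to prune to")

        def copy(node: Node) -> Node | None:
            if node.is_tip:
                if node.label in keep:
                    return Node(node.label, node.length)
                return None
            kids = [k for k in (copy(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if node.length is not None:
                    child.length += node.length
                return child
            new = Node(node.label, node.length)
            for k in kids:
                new.add_child(k)
            return new

        new_root = copy(self.root)
        assert new_root is not None
        new_root.length = None
        return PhyloTree(new_root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_tips} tips, height={self.height:g})"


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Branch lengths are mandatory on every non-root branch; tip labels must
    be unique.  Raises :class:`NewickError` naming the offending token on
    malformed input.
    """
    if not text or not text.strip():
        raise NewickError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root edge length carries no information here
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Regime paintings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegimePainting:
    """Assignment of every branch to a selective regime.

    ``kind`` distinguishes the two all-``base`` models: ``"bm"`` is
    Brownian motion, ``"ou"`` with empty ``shift_tips`` is the
    single-optimum model (M0).
    """

    model_id: str
    kind: str  # "bm" | "ou"
    shift_tips: frozenset[str]
    regimes: Mapping[str, str]  # branch_id -> BASE | SHIFT
    root_regime: str

    @property
    def has_shift(self) -> bool:
        return bool(self.shift_tips)

    @property
    def n_regimes(self) -> int:
        labels = set(self.regimes.values())
        return max(1, len(labels))

    def regime_of(self, branch_id: str) -> str:
        return self.regimes[branch_id]

    def n_shift_branches(self) -> int:
        return sum(1 for r in self.regimes.values() if r == SHIFT)

    def rederive(self, tree: PhyloTree) -> "RegimePainting":
        """Re-paint the same tip scenario on another (e.g. pruned) tree.

        Shift tips absent from ``tree`` are dropped; an empty remainder
        yields an all-base painting (callers treat that as untestable for
        branch-shift models).
        """
        remaining = self.shift_tips & set(tree.tip_labels)
        if not self.has_shift or not remaining:
            regimes = {bid: BASE for bid in tree.branch_ids()}
            return RegimePainting(self.model_id, self.kind, frozenset(remaining),
                                  regimes, BASE)
        return paint_tips(tree, remaining, self.model_id, kind=self.kind)

    def to_tsv(self) -> str:
        lines = ["branch_id\tregime"]
        lines += [f"{bid}\t{reg}" for bid, reg in self.regimes.items()]
        return "\n".join(lines) + "\n"


def _paint_regimes(tree: PhyloTree, shift_tips: frozenset[str]) -> dict[str, str]:
    regimes = {}
    for node in tree.preorder:
        if node is tree.root:
            continue
        shifted = tree.tipset(node) <= shift_tips
        regimes[tree.branch_id(node)] = SHIFT if shifted else BASE
    return regimes


def paint_tips(tree: PhyloTree, shift_tips: Iterable[str], model_id: str,
               kind: str = "ou") -> RegimePainting:
    """Paint ``shift`` on every branch whose subtree tips all lie in
    ``shift_tips``.

    For a monophyletic tip set this is the clade plus its stem branch; for
    a non-monophyletic set it is the union of maximal clades (each with its
    stem), e.g. the Dwil + Drosophila-subgenus scenario (M6).
    """
    shift_tips = frozenset(shift_tips)
    if not shift_tips:
        raise PaintingError("shift_tips must be non-empty")
    unknown = shift_tips - set(tree.tip_labels)
    if unknown:
        raise PaintingError(f"unknown tips: {sorted(unknown)}")
    regimes = _paint_regimes(tree, shift_tips)
    root_regime = SHIFT if shift_tips == frozenset(tree.tip_labels) else BASE
    return RegimePainting(model_id, kind, shift_tips, regimes, root_regime)


def paint_clade(tree: PhyloTree, shift_tips: Iterable[str],
                model_id: str) -> RegimePainting:
    """Like :func:`paint_tips` but requires ``shift_tips`` to be
    monophyletic in ``tree`` (errors otherwise)."""
    shift_tips = frozenset(shift_tips)
    mrca = tree.mrca(shift_tips)  # validates non-empty and known tips
    clade = tree.tipset(mrca)
    if clade != shift_tips:
        raise PaintingError(
            f"tips {sorted(shift_tips)} are not monophyletic: their MRCA also "
            f"contains {sorted(clade - shift_tips)}"
        )
    return paint_tips(tree, shift_tips, model_id)


def bm_painting(tree: PhyloTree) -> RegimePainting:
    regimes = {bid: BASE for bid in tree.branch_ids()}
    return RegimePainting("BM", "bm", frozenset(), regimes, BASE)


def m0_painting(tree: PhyloTree) -> RegimePainting:
    regimes = {bid: BASE for bid in tree.branch_ids()}
    return RegimePainting("M0", "ou", frozenset(), regimes, BASE)


# ---------------------------------------------------------------------------
# Built-in 12-species Drosophila scenarios
# ---------------------------------------------------------------------------

DROSOPHILA_12 = [
    "Dmel", "Dsim", "Dsec", "Dyak", "Dere", "Dana",
    "Dpse", "Dper", "Dwil", "Dmoj", "Dvir", "Dgri",
]

_SPECIES_FULL = {
    "Dmel": "melanogaster", "Dsim": "simulans", "Dsec": "sechellia",
    "Dyak": "yakuba", "Dere": "erecta", "Dana": "ananassae",
    "Dpse": "pseudoobscura", "Dper": "persimilis", "Dwil": "willistoni",
    "Dmoj": "mojavensis", "Dvir": "virilis", "Dgri": "grimshawi",
}

#: Shift-tip sets of the ten branch-shift scenarios (M1 = melanogaster
#: subgroup ... M10 = D. virilis specific).
BUILTIN_SHIFT_TIPS: dict[str, frozenset[str]] = {
    "M1": frozenset({"Dmel", "Dsim", "Dsec", "Dyak", "Dere"}),
    "M2": frozenset({"Dmel", "Dsim", "Dsec", "Dyak", "Dere", "Dana"}),
    "M3": frozenset({"Dmoj", "Dvir", "Dgri"}),
    "M4": frozenset({"Dmoj", "Dvir"}),
    "M5": frozenset({"Dpse", "Dper"}),
    "M6": frozenset({"Dwil", "Dmoj", "Dvir", "Dgri"}),
    "M7": frozenset({"Dsec"}),
    "M8": frozenset({"Dmel"}),
    "M9": frozenset({"Dpse"}),
    "M10": frozenset({"Dvir"}),
}


def _canonical_species(name: str) -> str | None:
    """Map a tip label to one of the 12 canonical short names, or None."""
    squashed = re.sub(r"[\s._-]", "", name).lower()
    for short, full in _SPECIES_FULL.items():
        if squashed in (short.lower(), "d" + full, "drosophila" + full, full):
            return short
    return None


def builtin_regimes(tree: PhyloTree,
                    aliases: Mapping[str, str] | None = None
                    ) -> list[RegimePainting]:
    """The 12 built-in paintings (BM, M0, M1..M10) on ``tree``.

    ``tree`` must contain all 12 Drosophila species, recognized either by
    the canonical short names (``Dmel``...), common long forms
    (``D. melanogaster``, ``dmel``...), or an explicit ``aliases`` mapping
    of tip label -> canonical short name.
    """
    aliases = dict(aliases or {})
    to_tip: dict[str, str] = {}
    for label in tree.tip_labels:
        canon = aliases.get(label) or _canonical_species(label)
        if canon is not None:
            to_tip[canon] = label
    missing = [s for s in DROSOPHILA_12 if s not in to_tip]
    if missing:
        raise PaintingError(
            f"tree is missing required species: {missing} "
            f"(tips seen: {tree.tip_labels})"
        )
    paintings = [bm_painting(tree), m0_painting(tree)]
    for model_id in sorted(BUILTIN_SHIFT_TIPS, key=lambda m: int(m[1:])):
        tips = frozenset(to_tip[s] for s in BUILTIN_SHIFT_TIPS[model_id])
        paintings.append(paint_tips(tree, tips, model_id))
    return paintings


def drosophila_tree() -> PhyloTree:
    """The packaged 12-species Drosophila chronogram (branch lengths in My).

    The topology is the accepted one; the dates are round literature
    values, and any user newick can be substituted for all fitting.
    """
    text = resources.files("crmou.data").joinpath("dmel12.nwk").read_text()
    return parse_newick(text)
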