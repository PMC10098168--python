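"""Tree data model, Newick I/O, MAD rooting and clade analysis.

The tree class is deliberately small: nodes carry parent/child links, an
optional branch length (expected substitutions/site), and an optional age
(Ma).  Newick parsing is delegated to :mod:`dendropy`; serialization is a
direct recursive writer so that labels and lengths round-trip exactly.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "PhyloTree",
    "RootPlacement",
    "TaxonAnnotation",
    "NewickParseError",
    "Clade",
    "mad_root",
    "find_monophyletic_clades",
    "clade_composition",
    "subsample_clades",
    "read_annotations",
    "write_annotations",
]

RANK_NAMES = ("genus", "order", "class", "phylum", "domain")
_UNKNOWN = {"", "na", "nan", "none", "unknown", "?"}


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class Node:
    """A single tree node; ``length`` is the edge to ``parent``."""

    __slots__ = ("label", "length", "parent", "children", "age")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: List["Node"] = []
        self.age: Optional[float] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length} age={self.age}>"


@dataclass(frozen=True)
class RootPlacement:
    """Optimal root position on a branch found by MAD rooting.

    ``edge_tips`` is the tip bipartition on the child side of the branch;
    ``rho`` is the distance of the root from the child endpoint.
    """

    edge_tips: frozenset
    rho: float
    branch_length: float
    mad: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= self.branch_length + 1e-12):
            raise ValueError("rho outside [0, branch length]")
        if self.mad < 0:
            raise ValueError("mad must be non-negative")


@dataclass
class TaxonAnnotation:
    """Taxonomic rank assignments for one tip."""

    label: str
    ranks: Dict[str, str] = field(default_factory=dict)

    def value(self, rank: str) -> Optional[str]:
        v = self.ranks.get(rank)
        if v is None or str(v).strip().lower() in _UNKNOWN:
            return None
        return str(v)


@dataclass
class Clade:
    """A labeled clade: the subtended tips plus the shared/majority value."""

    tips: Tuple[str, ...]
    value: Optional[str]
    share: float
    node: Node


class PhyloTree:
    """Rooted tree with unique tip labels.

    Branch lengths (if present) are non-negative; node ages (if present)
    describe an ultrametric chronogram with tips at age 0.
    """

    def __init__(self, root: Node):
        self.root = root
        self._check_tip_labels()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string (single-quoted labels supported)."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            offset = ""
            col = getattr(exc, "col_num", None)
            line = getattr(exc, "line_num", None)
            if col is not None:
                offset = f" (line {line}, column {col})"
            raise NewickParseError(f"malformed Newick{offset}: {exc}") from exc

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        """Serialize; float lengths use ``repr`` so they round-trip exactly."""

        def fmt_label(label: Optional[str]) -> str:
            if label is None:
                return ""
            if re.search(r"[\s()\[\]{}:;,']", label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def walk(node: Node) -> str:
            if node.is_tip:
                s = fmt_label(node.label)
            else:
                s = "(" + ",".join(walk(c) for c in node.children) + ")" + fmt_label(node.label)
            if node.length is not None:
                s += f":{node.length!r}"
            return s

        return walk(self.root) + ";"

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- traversal

    def postorder(self) -> Iterator[Node]:
        stack: List[Tuple[Node, bool]] = [(self.root, False)]
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
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> List[str]:
        return [n.label for n in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def find_tip(self, label: str) -> Node:
        for node in self.postorder():
            if node.is_tip and node.label == label:
                return node
        raise KeyError(f"tip {label!r} not in tree")

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        below: Dict[int, Set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = {node.label} & want
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if below[id(node)] == want:
                return node
        raise RuntimeError("unreachable")  # pragma: no cover

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.age = node.age
            for child in node.children:
                new.add_child(dup(child))
            return new

        return PhyloTree(dup(self.root))

    # ---------------------------------------------------------- invariants

    def _check_tip_labels(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")

    def has_ages(self) -> bool:
        return all(n.age is not None for n in self.postorder())

    def validate_ages(self, atol: float = 1e-9) -> None:
        """Check chronogram invariants: parent >= child, tips at 0."""
        for node in self.postorder():
            if node.age is None:
                raise ValueError("node ages missing")
            if node.is_tip and abs(node.age) > atol:
                raise ValueError(f"tip {node.label!r} has age {node.age} != 0")
            for child in node.children:
                if node.age < child.age - atol:
                    raise ValueError("parent age < child age")

    def set_lengths_from_ages(self) -> None:
        for node in self.postorder():
            if node.parent is not None:
                node.length = node.parent.age - node.age

    def tip_distance_matrix(self) -> Tuple[List[str], np.ndarray]:
        """All pairwise tip path distances along branch lengths."""
        labels = self.tip_labels
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))
        below: Dict[int, List[Tuple[int, float]]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = [(idx[node.label], 0.0)]
            else:
                groups = [
                    [(i, d + (c.length or 0.0)) for i, d in below[id(c)]]
                    for c in node.children
                ]
                for ga, gb in itertools.combinations(groups, 2):
                    for i, di in ga:
                        for j, dj in gb:
                            dist[i, j] = dist[j, i] = di + dj
                below[id(node)] = [pair for g in groups for pair in g]
        return labels, dist


# ======================================================================
# MAD rooting
# ======================================================================


def _unrooted_edges(tree: PhyloTree):
    """Undirected adjacency of the tree, merging a bifurcating root.

    Returns (adjacency, edges) where ``edges`` enumerates each undirected
    branch once, in postorder of the input tree, as
    ``(child_node, other_node, length)`` — ``child_node`` is the postorder
    (child-side) endpoint.
    """
    root = tree.root
    merge = len(root.children) == 2
    adjacency: Dict[int, List[Tuple[Node, float]]] = {}
    nodes: Dict[int, Node] = {}

    def add_edge(a: Node, b: Node, length: float) -> None:
        adjacency.setdefault(id(a), []).append((b, length))
        adjacency.setdefault(id(b), []).append((a, length))
        nodes[id(a)] = a
        nodes[id(b)] = b

    edges: List[Tuple[Node, Node, float]] = []
    merged_pair = None
    if merge:
        a, b = root.children
        merged_pair = (id(a), id(b))
        length = (a.length or 0.0) + (b.length or 0.0)
        add_edge(a, b, length)
    seen_merged = False
    for node in tree.postorder():
        if node.parent is None:
            continue
        if merge and node.parent is root:
            if not seen_merged:
                a, b = root.children
                edges.append((a, b, (a.length or 0.0) + (b.length or 0.0)))
                seen_merged = True
            continue
        add_edge(node, node.parent, node.length or 0.0)
        edges.append((node, node.parent, node.length or 0.0))
    return adjacency, edges, merged_pair


def _distances_from(node: Node, adjacency) -> Dict[int, float]:
    dist = {id(node): 0.0}
    stack = [node]
    while stack:
        cur = stack.pop()
        for nbr, length in adjacency[id(cur)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(cur)] + length
                stack.append(nbr)
    return dist


def _tipset_side(child: Node, other: Node, adjacency) -> Set[int]:
    """ids of tip nodes reachable from ``child`` without crossing the edge."""
    seen = {id(child), id(other)}
    tips = set()
    stack = [child]
    if child.is_tip:
        tips.add(id(child))
    while stack:
        cur = stack.pop()
        for nbr, _ in adjacency[id(cur)]:
            if id(nbr) in seen:
                continue
            seen.add(id(nbr))
            if nbr.is_tip:
                tips.add(id(nbr))
            stack.append(nbr)
    return tips


def _mad_edge_score(t, d_child, d_other, dmat):
    """Deviation sums for one candidate branch.

    ``d_child``/``d_other`` are tip distances (numpy vectors over all tips)
    to the two endpoints; entries are NaN for tips on the far side.  Returns
    (rho*, sum of squared deviations over all pairs).
    """
    in_s = ~np.isnan(d_child)
    s_idx = np.flatnonzero(in_s)
    o_idx = np.flatnonzero(~in_s)

    ssq = 0.0
    # same-side pairs: deviation independent of rho
    for idx, dvec in ((s_idx, d_child), (o_idx, d_other)):
        if len(idx) > 1:
            dv = dvec[idx]
            diff = np.abs(dv[:, None] - dv[None, :])
            denom = dmat[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            r = diff[iu] / denom[iu]
            ssq += float(np.sum(r * r))

    # spanning pairs
    di = d_child[s_idx][:, None]
    dj = d_other[o_idx][None, :]
    D = di + dj + t
    if t > 0:
        num = float(np.sum((D - 2.0 * di) / (D * D)))
        den = float(np.sum(1.0 / (D * D)))
        rho = min(max(num / (2.0 * den), 0.0), t)
    else:
        rho = 0.0
    r_span = (2.0 * (di + rho) - D) / D
    ssq += float(np.sum(r_span * r_span))
    return rho, ssq


def mad_root(tree: PhyloTree) -> Tuple[RootPlacement, PhyloTree]:
    """Root a tree by Minimal Ancestor Deviation.

    For every branch and root position the relative deviation of each tip
    pair from its midpoint is ``|2 d(a,i)/(d(a,i)+d(a,j)) - 1|`` with *a*
    the pair's ancestor under that rooting; the returned placement
    minimizes the root-mean-square deviation.  Ties between branches are
    broken by postorder enumeration (first wins).
    """
    tips = tree.tips()
    if len(tips) < 3:
        raise ValueError("MAD rooting needs at least 3 tips")
    for node in tree.postorder():
        if node.parent is not None and node.length is None:
            raise ValueError(f"branch length missing above {node.label!r}")
    labels, dmat = tree.tip_distance_matrix()
    if not np.any(dmat > 0):
        raise ValueError("all branch lengths are zero: no metric information")
    tip_index = {l: i for i, l in enumerate(labels)}

    adjacency, edges, _ = _unrooted_edges(tree)
    n = len(labels)
    npairs = n * (n - 1) // 2

    best = None
    for child, other, t in edges:
        side = _tipset_side(child, other, adjacency)
        dc_all = _distances_from(child, adjacency)
        do_all = _distances_from(other, adjacency)
        d_child = np.full(n, np.nan)
        d_other = np.full(n, np.nan)
        for tip in tips:
            i = tip_index[tip.label]
            if id(tip) in side:
                d_child[i] = dc_all[id(tip)]
            else:
                d_other[i] = do_all[id(tip)]
        rho, ssq = _mad_edge_score(t, d_child, d_other, dmat)
        mad = math.sqrt(ssq / npairs)
        if best is None or mad < best[0] - 1e-15:
            tipset = frozenset(labels[i] for i in np.flatnonzero(~np.isnan(d_child)))
            best = (mad, child, other, t, rho, tipset)

    mad, child, other, t, rho, tipset = best
    placement = RootPlacement(edge_tips=tipset, rho=min(rho, t), branch_length=t, mad=mad)
    rooted = _reroot_at(tree, adjacency, child, other, t, rho)
    return placement, rooted


def _reroot_at(tree: PhyloTree, adjacency, child: Node, other: Node, t: float, rho: float) -> PhyloTree:
    """Build a new rooted tree with the root ``rho`` from ``child`` on the edge."""

    def build(node: Node, came_from: Node, length: float) -> Node:
        new = Node(node.label, length)
        for nbr, elen in adjacency[id(node)]:
            if nbr is came_from:
                continue
            new.add_child(build(nbr, node, elen))
        return new

    root = Node(label=None, length=None)
    root.add_child(build(child, other, rho))
    root.add_child(build(other, child, t - rho))
    return PhyloTree(root)


# ======================================================================
# Clade analysis
# ======================================================================


def _rank_values(
    tree: PhyloTree, annotations: Dict[str, TaxonAnnotation], rank: str
) -> Dict[str, Optional[str]]:
    if not any(rank in a.ranks for a in annotations.values()):
        raise KeyError(f"rank {rank!r} absent from annotations")
    values: Dict[str, Optional[str]] = {}
    for label in tree.tip_labels:
        ann = annotations.get(label)
        values[label] = ann.value(rank) if ann is not None else None
    return values


def find_monophyletic_clades(
    tree: PhyloTree, annotations: Dict[str, TaxonAnnotation], rank: str
) -> List[Clade]:
    """Maximal clades whose tips all share one value at ``rank``.

    Tips with unknown rank never join a clade; returned clades are
    node-disjoint (topmost qualifying nodes, preorder).
    """
    values = _rank_values(tree, annotations, rank)
    info: Dict[int, Tuple[Set[str], bool, List[str]]] = {}
    for node in tree.postorder():
        if node.is_tip:
            v = values[node.label]
            info[id(node)] = ({v} if v is not None else set(), v is None, [node.label])
        else:
            vals: Set[str] = set()
            unknown = False
            tips: List[str] = []
            for c in node.children:
                cv, cu, ct = info[id(c)]
                vals |= cv
                unknown = unknown or cu
                tips.extend(ct)
            info[id(node)] = (vals, unknown, tips)

    clades: List[Clade] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        vals, unknown, tips = info[id(node)]
        if len(vals) == 1 and not unknown:
            clades.append(Clade(tips=tuple(tips), value=next(iter(vals)), share=1.0, node=node))
        else:
            stack.extend(reversed(node.children))
    return clades


def clade_composition(
    tree: PhyloTree,
    annotations: Dict[str, TaxonAnnotation],
    rank: str,
    threshold: float = 0.67,
) -> List[Clade]:
    """Maximal clades where one rank value's tip share strictly exceeds
    ``threshold``.  Unannotated tips count in the denominator."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    values = _rank_values(tree, annotations, rank)
    counts: Dict[int, Dict[str, int]] = {}
    ntips: Dict[int, int] = {}
    tips_below: Dict[int, List[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            v = values[node.label]
            counts[id(node)] = {v: 1} if v is not None else {}
            ntips[id(node)] = 1
            tips_below[id(node)] = [node.label]
        else:
            acc: Dict[str, int] = {}
            tot = 0
            tl: List[str] = []
            for c in node.children:
                for v, k in counts[id(c)].items():
                    acc[v] = acc.get(v, 0) + k
                tot += ntips[id(c)]
                tl.extend(tips_below[id(c)])
            counts[id(node)] = acc
            ntips[id(node)] = tot
            tips_below[id(node)] = tl

    out: List[Clade] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        acc = counts[id(node)]
        if acc:
            value, best = max(acc.items(), key=lambda kv: (kv[1], kv[0]))
            share = best / ntips[id(node)]
            if share > threshold:
                out.append(
                    Clade(tips=tuple(tips_below[id(node)]), value=value, share=share, node=node)
                )
                continue
        stack.extend(reversed(node.children))
    return out


def subsample_clades(
    tree: PhyloTree, clades: Sequence, k: int
) -> Set[str]:
    """Retain ``min(k, size)`` tips per clade plus all background tips.

    k=1 keeps the tip with the longest terminal branch; k=2 the maximally
    divergent pair; k>2 extends the pair greedily (farthest point).  Ties
    break lexicographically by label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels, dmat = tree.tip_distance_matrix()
    idx = {l: i for i, l in enumerate(labels)}
    term_len = {n.label: (n.length or 0.0) for n in tree.tips()}

    retained: Set[str] = set()
    in_clade: Set[str] = set()
    for clade in clades:
        members = sorted(clade.tips if isinstance(clade, Clade) else clade)
        in_clade.update(members)
        if len(members) <= k:
            retained.update(members)
            continue
        if k == 1:
            retained.add(max(members, key=lambda l: (term_len[l], _neg_lex(l))))
            continue
        # maximally divergent pair, deterministic tie-break
        best_pair = None
        for a, b in itertools.combinations(members, 2):
            d = dmat[idx[a], idx[b]]
            key = (d, _neg_lex(a), _neg_lex(b))
            if best_pair is None or key > best_pair[0]:
                best_pair = (key, (a, b))
        chosen = list(best_pair[1])
        while len(chosen) < k:
            rest = [m for m in members if m not in chosen]
            nxt = max(
                rest, key=lambda l: (min(dmat[idx[l], idx[c]] for c in chosen), _neg_lex(l))
            )
            chosen.append(nxt)
        retained.update(chosen)

    retained.update(set(tree.tip_labels) - in_clade)
    return retained


class _neg_lex(str):
    """Wrapper giving reversed lexicographic order so that ``max`` picks the
    lexicographically smallest label on ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ======================================================================
# Annotation I/O
# ======================================================================


def read_annotations(path) -> Dict[str, TaxonAnnotation]:
    """Read a TSV taxon table (tip_label + rank columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "tip_label" not in df.columns:
        raise ValueError("annotation table must have a 'tip_label' column")
    out = {}
    for _, row in df.iterrows():
        ranks = {r: row[r] for r in RANK_NAMES if r in df.columns}
        out[row["tip_label"]] = TaxonAnnotation(label=row["tip_label"], ranks=ranks)
    return out


def write_annotations(annotations: Dict[str, TaxonAnnotation], path) -> None:
    rows = []
    for label, ann in annotations.items():
        row = {"tip_label": label}
        row.update({r: ann.ranks.get(r, "") for r in RANK_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def clade_report(clades: Sequence[Clade]) -> pd.DataFrame:
    """Tabular clade report (clade id, size, majority group, share)."""
    return pd.DataFrame(
        [
            {
                "clade_id": i,
                "size": len(c.tips),
                "group": c.value,
                "share": round(c.share, 6),
                "tips": ",".join(c.tips),
            }
            for i, c in enumerate(clades)
        ]
    )
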