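"""Timed multifurcating genealogies and their sufficient statistics.

Time runs from 0 at the most recent tip and increases into the past.  A
heterochronous genealogy is summarized by its sufficient statistics:
sampling times ``s`` with counts ``n``, coalescent times ``t`` and merger
block sizes ``m``.  The number of extant ancestral lineages is the step
function

    A(t) = sum_l n_l 1(s_l < t) - sum_k (m_k - 1) 1(t_k < t),

right-continuity convention: at a sampling time the new tips are not yet
counted; at a coalescent time the merger has not yet been applied.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "SamplingSchedule",
    "CoalescentData",
    "TreeNode",
    "TimedTree",
    "lineage_count",
    "read_newick",
    "write_newick",
    "sufficient_stats",
    "stats_to_tsv",
    "stats_from_tsv",
]

DEFAULT_COLLAPSE_TOL = 1e-8
_TIE_NUDGE = 1e-9


@dataclass(frozen=True)
class SamplingSchedule:
    """Sampling times ``s`` (s[0] = 0, strictly increasing) and counts ``n``."""

    s: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        n = np.asarray(self.n, dtype=int)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "n", n)
        if s.ndim != 1 or n.shape != s.shape:
            raise ValueError("s and n must be 1-d arrays of equal length")
        if s.size == 0 or s[0] != 0.0:
            raise ValueError("first sampling time must be 0")
        if np.any(np.diff(s) <= 0.0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(n <= 0):
            raise ValueError("sample counts must be positive")
        if int(n.sum()) < 2:
            raise ValueError("need at least 2 samples in total")

    @property
    def L(self) -> int:
        return int(self.s.size)

    @property
    def total(self) -> int:
        return int(self.n.sum())

    @classmethod
    def isochronous(cls, n: int) -> "SamplingSchedule":
        return cls(np.array([0.0]), np.array([n]))


@dataclass(frozen=True)
class CoalescentData:
    """Sufficient statistics (s, n, t, m) of a multifurcating genealogy."""

    schedule: SamplingSchedule
    t: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        m = np.asarray(self.m, dtype=int)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "m", m)
        if t.ndim != 1 or m.shape != t.shape:
            raise ValueError("t and m must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("need at least one coalescent event")
        if t[0] <= 0.0 or np.any(np.diff(t) <= 0.0):
            raise ValueError("coalescent times must be strictly increasing and > 0")
        if np.any(m < 2):
            raise ValueError("block sizes must be >= 2")
        n_total = self.schedule.total
        if int((m - 1).sum()) != n_total - 1:
            raise ValueError(
                f"sum(m - 1) = {(m - 1).sum()} but n - 1 = {n_total - 1}: "
                "genealogy does not reach a single MRCA"
            )
        a_before = lineage_count(self, t)
        if np.any(m > a_before):
            bad = int(np.argmax(m > a_before))
            raise ValueError(
                f"block size m[{bad}]={m[bad]} exceeds extant lineages "
                f"A(t)={a_before[bad]} at t={t[bad]}"
            )

    @property
    def K(self) -> int:
        return int(self.t.size)

    @property
    def tmrca(self) -> float:
        return float(self.t[-1])


def lineage_count(data: CoalescentData, t) -> np.ndarray | int:
    """A(t): number of extant ancestral lineages just before time t."""
    tq = np.asarray(t, dtype=float)
    scalar = tq.ndim == 0
    tq = np.atleast_1d(tq)
    added = (data.schedule.s[None, :] < tq[:, None]) @ data.schedule.n
    removed = (data.t[None, :] < tq[:, None]) @ (data.m - 1)
    a = added - removed
    return int(a[0]) if scalar else a


class TreeNode:
    """Node of a timed tree; ``time`` increases into the past."""

    __slots__ = ("time", "label", "children")

    def __init__(self, time: float, label: str | None = None,
                 children: list["TreeNode"] | None = None):
        self.time = float(time)
        self.label = label
        self.children = children if children is not None else []

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class TimedTree:
    """Rooted multifurcating tree with node times (0 = most recent tip)."""

    root: TreeNode

    def walk(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.walk() if n.is_leaf()]

    def internals(self) -> list[TreeNode]:
        return [n for n in self.walk() if not n.is_leaf()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())


def _collapse(node: TreeNode, tol: float) -> None:
    """Splice out internal children whose subtending branch is <= tol."""
    changed = True
    while changed:
        changed = False
        new_children: list[TreeNode] = []
        for child in node.children:
            if not child.is_leaf() and (node.time - child.time) <= tol:
                new_children.extend(child.children)
                changed = True
            else:
                new_children.append(child)
        node.children = new_children
    for child in node.children:
        if not child.is_leaf():
            _collapse(child, tol)


def read_newick(text: str, collapse_tol: float = DEFAULT_COLLAPSE_TOL) -> TimedTree:
    """Parse a Newick string into a :class:`TimedTree`.

    Node times are computed from branch lengths with the most recent tip at
    time 0.  Internal branches of length <= ``collapse_tol`` are collapsed
    into multifurcations (maximum-likelihood trees commonly encode
    polytomies as near-zero branches).
    """
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    # depth of each node from the root along edge lengths
    depths: dict = {}
    max_depth = 0.0
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            if bl < 0:
                raise ValueError(f"negative branch length {bl} in Newick input")
            depths[nd] = depths[nd.parent_node] + bl
        if nd.is_leaf():
            max_depth = max(max_depth, depths[nd])

    def convert(nd) -> TreeNode:
        time = max_depth - depths[nd]
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else None
            return TreeNode(time, label=label)
        return TreeNode(time, children=[convert(c) for c in nd.child_nodes()])

    root = convert(dtree.seed_node)
    _collapse(root, collapse_tol)
    return TimedTree(root)


def _newick_of(node: TreeNode, parent_time: float | None) -> str:
    if node.is_leaf():
        body = node.label if node.label else ""
    else:
        body = "(" + ",".join(_newick_of(c, node.time) for c in node.children) + ")"
    if parent_time is None:
        return body
    return f"{body}:{parent_time - node.time:.12g}"


def write_newick(tree: TimedTree) -> str:
    """Serialize a :class:`TimedTree` to Newick with branch lengths."""
    return _newick_of(tree.root, None) + ";"


def sufficient_stats(
    tree: TimedTree, collapse_tol: float = DEFAULT_COLLAPSE_TOL
) -> CoalescentData:
    """Extract (s, n, t, m) from a timed tree.

    Tips are grouped into sampling times within ``collapse_tol``; block
    sizes are internal-node out-degrees.  Exact ties between event times
    (or between an event and a sampling time) are perturbed pastward by
    1e-9 with a warning, since the coalescent density assumes a simple
    point process.
    """
    tip_times = np.sort([tip.time for tip in tree.tips()])
    groups: list[list[float]] = [[tip_times[0]]]
    for tt in tip_times[1:]:
        if tt - groups[-1][0] <= collapse_tol:
            groups[-1].append(tt)
        else:
            groups.append([tt])
    s = np.array([g[0] for g in groups])
    s[0] = 0.0
    n = np.array([len(g) for g in groups])

    events = sorted((nd.time, len(nd.children)) for nd in tree.internals())
    t = np.array([e[0] for e in events])
    m = np.array([e[1] for e in events])

    # enforce almost-sure distinctness of the point process
    nudged = False
    s_set = s
    for k in range(t.size):
        lo = t[k - 1] if k > 0 else 0.0
        if t[k] <= lo:
            t[k] = lo + _TIE_NUDGE
            nudged = True
        if np.any(np.abs(s_set - t[k]) < _TIE_NUDGE / 2):
            t[k] = t[k] + _TIE_NUDGE
            nudged = True
    if nudged:
        warnings.warn(
            "coincident event times perturbed by 1e-9 to restore distinctness",
            stacklevel=2,
        )
    return CoalescentData(SamplingSchedule(s, n), t, m)


def stats_to_tsv(data: CoalescentData) -> str:
    """Tabular export: rows (event_type, time, count_or_blocksize)."""
    buf = io.StringIO()
    buf.write("event_type\ttime\tcount_or_blocksize\n")
    rows = [("sample", float(s), int(c)) for s, c in zip(data.schedule.s, data.schedule.n)]
    rows += [("coalescent", float(t), int(m)) for t, m in zip(data.t, data.m)]
    rows.sort(key=lambda r: r[1])
    for kind, time, val in rows:
        buf.write(f"{kind}\t{time:.12g}\t{val}\n")
    return buf.getvalue()


def stats_from_tsv(text: str) -> CoalescentData:
    """Inverse of :func:`stats_to_tsv`."""
    s, n, t, m = [], [], [], []
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    for line in lines[1:]:
        kind, time, val = line.split("\t")
        if kind == "sample":
            s.append(float(time))
            n.append(int(val))
        elif kind == "coalescent":
            t.append(float(time))
            m.append(int(val))
        else:
            raise ValueError(f"unknown event type {kind!r}")
    order_s = np.argsort(s)
    order_t = np.argsort(t)
    schedule = SamplingSchedule(np.asarray(s)[order_s], np.asarray(n)[order_s])
    return CoalescentData(schedule, np.asarray(t)[order_t], np.asarray(m)[order_t])
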