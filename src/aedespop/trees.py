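"""Neighbor-joining trees, Jukes-Cantor distances and Newick serialization.

The Saitou-Nei neighbor-joining algorithm is implemented directly: at
each step the pair (i, j) minimising

    Q_ij = (m - 2) d_ij - r_i - r_j      (r = row sums, m = active nodes)

is joined, with branch lengths from the standard three-point formulas.
On an additive matrix this recovers the generating topology and branch
lengths exactly.  F_ST matrices are not additive (and may contain
negative entries before clamping); trees built from them are summaries
of between-population relationships, not phylogenies.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Clade:
    """A node of a (rooted-representation) tree.

    ``length`` is the branch to the parent; the root's length is unused.
    """

    name: str | None = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with a trifurcating root (NJ convention)."""

    root: Clade

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def _edges(self):
        """(parent, child) pairs in preorder."""
        out = []

        def walk(node):
            for c in node.children:
                out.append((node, c))
                walk(c)

        walk(self.root)
        return out

    def path_distances(self) -> "DistanceMatrix":
        """Leaf-to-leaf path-length matrix (sum of branch lengths)."""
        # depth of every node from root + leaf lists per subtree
        labels = self.leaf_names()
        index = {n: i for i, n in enumerate(labels)}
        k = len(labels)
        dist = np.zeros((k, k))

        def walk(node, depth):
            """Returns {leaf index: depth} under node."""
            if node.is_leaf:
                return {index[node.name]: depth}
            below: dict[int, float] = {}
            merged: dict[int, float] = {}
            for c in node.children:
                sub = walk(c, depth + c.length)
                for i, di in sub.items():
                    for j, dj in merged.items():
                        d = (di - depth) + (dj - depth)
                        dist[i, j] = dist[j, i] = d
                merged.update(sub)
            below.update(merged)
            return below

        walk(self.root, 0.0)
        return DistanceMatrix(labels, dist)

    def bipartitions(self) -> list[tuple[frozenset, float]]:
        """Leaf-set splits induced by internal edges, with edge lengths.

        Each split is reported as the frozenset of leaf names on the
        child side; trivial (single-leaf) splits are excluded.
        """
        all_leaves = frozenset(self.leaf_names())
        out = []
        for _parent, child in self._edges():
            side = frozenset(l.name for l in child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                out.append((side, child.length))
        return out


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distance matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def nj(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break toward the lowest index pair in the
    current node ordering (input label order, joined nodes appended).
    A negative branch length is clamped to zero with the deficit moved
    to its sibling branch, so path lengths through the join are kept.
    """
    dm.validate()
    m = len(dm.labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: list[Clade] = [Clade(name=l) for l in dm.labels]
    d = dm.values.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin is row-major, so equal minima resolve to lowest (i, j)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Clade(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = du[keep]
        d[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final three nodes around a trifurcating root
    v0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    v1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    v2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, v in zip(nodes, (v0, v1, v2)):
        node.length = max(v, 0.0)
    return Tree(root=Clade(children=nodes))


def sequence_distance(records: list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise Jukes-Cantor (JC69) distances from aligned sequences.

    Positions where either sequence holds a gap or ambiguity code are
    excluded pairwise.  d = -(3/4) ln(1 - (4/3) p-hat); saturation
    (p-hat >= 0.75) raises an error.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [name for name, _ in records]
    length = len(records[0][1])
    for name, seq in records:
        if len(seq) != length:
            raise ValueError(f"sequence {name!r} length {len(seq)} != {length}")
    arr = np.frombuffer(
        "".join(seq.upper() for _, seq in records).encode(), dtype="S1"
    ).reshape(len(records), length)
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    k = len(records)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            n_valid = int(both.sum())
            if n_valid == 0:
                raise ValueError(
                    f"no comparable positions between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / n_valid
            if p >= 0.75:
                raise ValueError(
                    f"JC69 saturated between {labels[i]!r} and {labels[j]!r} "
                    f"(p-hat = {p:.3f} >= 0.75)"
                )
            d = -0.75 * math.log1p(-4.0 * p / 3.0)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat)


_NEEDS_QUOTE = set(" \t()[]':;,")


def _format_label(name: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: Tree, path=None) -> str:
    """Serialize to Newick with full-precision branch lengths.

    ``parse_newick(write_newick(t))`` reproduces the tree exactly.
    """

    def fmt(node: Clade) -> str:
        if node.is_leaf:
            body = _format_label(node.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _format_label(node.name)
        return body + f":{node.length:.17g}"

    text = "(" + ",".join(fmt(c) for c in tree.root.children) + ");"
    if not tree.root.children:  # pragma: no cover - degenerate
        text = fmt(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def parse_newick(text: str) -> Tree:
    """Parse a Newick string produced by :func:`write_newick`."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_clade() -> Clade:
        nonlocal pos
        node = Clade()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        node.name = parse_label() or None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in ":,();":
            pos += 1
        return s[start:pos]

    root = parse_clade()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick string at offset {pos}")
    return Tree(root=root)


def split_by_longest_edges(tree: Tree, n_groups: int) -> list[set[str]]:
    """Partition leaves by cutting the longest internal branches.

    The ``n_groups - 1`` longest edges joining two internal nodes are
    removed (ties resolved by preorder position) and the connected leaf
    sets returned, largest group first.
    """
    leaves = tree.leaf_names()
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(leaves):
        raise ValueError("more groups requested than leaves")
    if n_groups == 1:
        return [set(leaves)]
    edges = tree._edges()
    internal = [
        (child.length, k)
        for k, (_p, child) in enumerate(edges)
        if not child.is_leaf
    ]
    if len(internal) < n_groups - 1:
        raise ValueError("tree has too few internal edges to cut")
    internal.sort(key=lambda t: (-t[0], t[1]))
    cut = {k for _, k in internal[: n_groups - 1]}

    # union-find over nodes, skipping cut edges
    parent_map: dict[int, int] = {}

    def find(x):
        while parent_map.get(x, x) != x:
            parent_map[x] = parent_map.get(parent_map[x], parent_map[x])
            x = parent_map[x]
        return x

    ids = {id(tree.root): 0}
    counter = [0]

    def nid(node):
        key = id(node)
        if key not in ids:
            counter[0] += 1
            ids[key] = counter[0]
        return ids[key]

    for k, (p, c) in enumerate(edges):
        a, b = nid(p), nid(c)
        if k in cut:
            continue
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_map[ra] = rb

    groups: dict[int, set[str]] = {}
    for leaf in tree.root.leaves():
        groups.setdefault(find(nid(leaf)), set()).add(leaf.name)
    return sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))
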