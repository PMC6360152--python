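"""Tamura-Nei distances, neighbor-joining trees, bootstrap support, lineages.

Distances use the TN93 substitution model with pairwise deletion: for each
sequence pair, only columns where both sequences carry an unambiguous base
are compared.  Trees are built by the Saitou-Nei neighbor-joining
agglomeration with a deterministic tie rule, and node support comes from
nonparametric bootstrap over alignment columns.  Query domains are placed
into labeled reference lineages via supported monophyletic groupings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# TN93 distance


def tn93_distance(a: str, b: str) -> tuple[float, int]:
    """Tamura-Nei (TN93) distance between two aligned nucleotide sequences.

    Columns with a gap or ambiguous base in either sequence are deleted
    pairwise.  Returns ``(distance, sites_used)``; the distance is ``nan``
    (flagged inapplicable) when no sites remain or the correction's log
    argument is non-positive (saturation).
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    return _tn93_from_counts(_pair_counts(_encode_nt(a), _encode_nt(b)))


def _encode_nt(s: str) -> np.ndarray:
    """Bases as 0..3; anything else (gap, N) as 4."""
    arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


def _pair_counts(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    mask = (ea < 4) & (eb < 4)
    idx = ea[mask].astype(np.int64) * 4 + eb[mask]
    return np.bincount(idx, minlength=16).reshape(4, 4).astype(float)


def _tn93_from_counts(counts: np.ndarray) -> tuple[float, int]:
    n = counts.sum()
    if n == 0:
        return math.nan, 0
    # base composition pooled over both sequences' retained sites
    freq = (counts.sum(axis=1) + counts.sum(axis=0)) / (2 * n)
    gA, gC, gG, gT = freq
    gR, gY = gA + gG, gC + gT
    P1 = (counts[0, 2] + counts[2, 0]) / n  # A<->G transitions
    P2 = (counts[1, 3] + counts[3, 1]) / n  # C<->T transitions
    Q = (counts.sum() - np.trace(counts) - P1 * n - P2 * n) / n  # transversions
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0, int(n)
    try:
        k1 = 2 * gA * gG / gR
        k2 = 2 * gC * gT / gY
        w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - Q / (2 * gR * gY)
        if w1 <= 0 or w2 <= 0 or w3 <= 0 or (k1 == 0 and P1 > 0) or (k2 == 0 and P2 > 0):
            return math.nan, int(n)
        d = 0.0
        if k1 > 0:
            d -= k1 * math.log(w1)
        if k2 > 0:
            d -= k2 * math.log(w2)
        d -= 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(w3)
    except (ValueError, ZeroDivisionError):
        return math.nan, int(n)
    return max(d, 0.0), int(n)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair effective site counts."""

    names: list[str]
    matrix: np.ndarray
    sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(np.diag(self.matrix), 0, equal_nan=False):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.names)

    def has_inapplicable(self) -> bool:
        return bool(np.isnan(self.matrix).any())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.names) + "\n")
            for name, row in zip(self.names, self.matrix):
                fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _distance_matrix_encoded(names: list[str], enc: np.ndarray) -> DistanceMatrix:
    n = len(names)
    mat = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d, s = _tn93_from_counts(_pair_counts(enc[i], enc[j]))
            mat[i, j] = mat[j, i] = d
            sites[i, j] = sites[j, i] = s
    return DistanceMatrix(names=names, matrix=mat, sites=sites)


def distance_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """All-pairs TN93 distance matrix over an aligned sequence dict."""
    names = list(alignment)
    enc = np.stack([_encode_nt(alignment[n]) for n in names])
    return _distance_matrix_encoded(names, enc)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class PhyloTree:
    """Unrooted tree with raw branch lengths and optional bootstrap support.

    Negative NJ branch-length estimates are retained internally and clamped
    to zero only at newick serialization.
    """

    tree: dendropy.Tree
    arbitrary_topology: bool = False

    @property
    def leaf_names(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def newick(self, clamp_negative: bool = True) -> str:
        t = self.tree.clone(depth=1)
        if clamp_negative:
            for e in t.preorder_edge_iter():
                if e.length is not None and e.length < 0:
                    e.length = 0.0
        return t.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, s: str) -> "PhyloTree":
        t = dendropy.Tree.get(data=s, schema="newick")
        return cls(tree=t)

    def path_length_matrix(self, names: Sequence[str]) -> np.ndarray:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(names)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.distance(taxa[names[i]], taxa[names[j]])
        return out


def nj_build(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    For an additive input matrix the output tree's path-length matrix
    reproduces the input exactly.  Ties in the Q criterion are broken
    deterministically toward the lowest (i, j) index pair in row-major
    order over the current node list.
    """
    if d.n < 3:
        raise ValueError("need at least 3 taxa")
    if d.has_inapplicable():
        bad = [d.names[i] for i in sorted(set(np.argwhere(np.isnan(d.matrix)).ravel()))]
        raise ValueError(
            "distance matrix has inapplicable entries; remove affected taxa: "
            + ", ".join(bad)
        )
    ns = dendropy.TaxonNamespace([dendropy.Taxon(label=n) for n in d.names])
    nodes = [dendropy.Node(taxon=t) for t in ns]
    mat = d.matrix.copy()
    active = list(range(len(nodes)))

    while len(active) > 2:
        m = len(active)
        sub = mat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin gives the lowest-index tie winner
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = mat[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        new = len(nodes)
        newrow = np.full(new, 0.0)
        grown = np.zeros((new, new))
        grown[: new - 1, : new - 1] = mat
        for k in active:
            if k in (i, j):
                continue
            grown[new - 1, k] = grown[k, new - 1] = 0.5 * (mat[i, k] + mat[j, k] - dij)
        mat = grown
        active = [k for k in active if k not in (i, j)] + [new - 1]

    i, j = active
    # join the last two nodes by a single internal edge
    a, b = nodes[i], nodes[j]
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    a.edge.length = None
    b.edge.length = mat[i, j]
    a.add_child(b)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=a)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as frozensets of the smaller-side leaf labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(
    alignment: Mapping[str, str], reps: int = 1000, seed: int = 1
) -> PhyloTree:
    """NJ tree with bootstrap support on internal nodes.

    Columns are resampled with replacement ``reps`` times; support is the
    percentage of replicate trees containing each internal bipartition of
    the point-estimate tree.  Taxa are canonically ordered internally so
    supports do not depend on input order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    names = sorted(alignment)
    seqs = {n: alignment[n] for n in names}
    enc = np.stack([_encode_nt(seqs[n]) for n in names])
    point = nj_build(_distance_matrix_encoded(names, enc))
    arbitrary = len(set(seqs.values())) == 1
    length = enc.shape[1]
    rng = np.random.default_rng(seed)

    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(point.tree)}
    for _ in range(reps):
        idx = rng.integers(0, length, size=length)
        try:
            rep_tree = nj_build(_distance_matrix_encoded(names, enc[:, idx]))
        except ValueError:
            continue  # saturated replicate
        rep_bps = _bipartitions(rep_tree.tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_leaves = frozenset(names)
    for node in point.tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
            node.label = f"{100.0 * counts[key] / reps:g}"
    return PhyloTree(tree=point.tree, arbitrary_topology=arbitrary)


# ---------------------------------------------------------------------------
# Lineage assignment


@dataclass
class LineageAssignment:
    query: str
    domain: str
    lineage: str  # I..V or "unresolved"
    support: float


def assign_lineage(
    queries: Mapping[str, str],
    references: Mapping[str, str],
    lineages: Mapping[str, str],
    domain: str = "",
    support_threshold: float = 70.0,
    reps: int = 100,
    seed: int = 1,
) -> list[LineageAssignment]:
    """Place query sequences into labeled reference lineages.

    A joint NJ tree with bootstrap support is built over queries plus
    references; each query receives the lineage of the smallest supported
    (>= threshold) monophyletic reference group that contains it, else
    ``unresolved``.  A reference lineage with fewer than two members
    triggers a nearest-reference fallback for that lineage.
    """
    overlap = set(queries) & set(references)
    if overlap:
        raise ValueError(f"query/reference name collision: {sorted(overlap)}")
    singleton_lineages = {
        lin for lin in set(lineages.values()) if sum(1 for v in lineages.values() if v == lin) < 2
    }
    if singleton_lineages:
        warnings.warn(
            f"reference lineages with <2 members: {sorted(singleton_lineages)}; "
            "nearest-reference fallback applies"
        )
    joint = {**queries, **references}
    tree = bootstrap_support(joint, reps=reps, seed=seed)

    all_leaves = frozenset(joint)
    # candidate groups: (size, lineage, support) per supported edge side
    edges: list[tuple[frozenset[str], float]] = []
    for node in tree.tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (1 < len(side) < len(all_leaves) - 1) or node.label is None:
            continue
        support = float(node.label)
        edges.append((side, support))
        edges.append((all_leaves - side, support))

    out: list[LineageAssignment] = []
    for q in queries:
        best: tuple[int, str, float] | None = None
        for side, support in edges:
            if q not in side or support < support_threshold:
                continue
            refs_in = {r for r in side if r in references}
            if not refs_in:
                continue
            lins = {lineages[r] for r in refs_in}
            if len(lins) != 1:
                continue
            cand = (len(side), next(iter(lins)), support)
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            # identity / singleton-lineage fallback: zero-distance reference
            for r in references:
                if queries[q] == references[r] or lineages[r] in singleton_lineages:
                    d, _ = tn93_distance(queries[q], references[r])
                    if d == 0.0:
                        best = (1, lineages[r], 100.0)
                        break
        if best is None:
            out.append(LineageAssignment(q, domain, "unresolved", 0.0))
        else:
            out.append(LineageAssignment(q, domain, best[1], best[2]))
    return out


def lineage_report(assignments: Sequence[LineageAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tdomain\tlineage\tsupport\n")
        for a in assignments:
            fh.write(f"{a.query}\t{a.domain}\t{a.lineage}\t{a.support:g}\n")
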