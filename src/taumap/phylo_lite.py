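"""Desk-scale distance phylogenetics: corrected distances, neighbor joining,
midpoint rooting and bootstrap bipartition support.

Distances use pairwise deletion (a column counts for a pair when both rows
are unambiguous residues), with three corrections:

* ``p``       — raw mismatch fraction
* ``poisson`` — d = -ln(1 - p)
* ``gamma``   — d = alpha * ((1 - p)^(-1/alpha) - 1), rate variation across
  sites with shape ``alpha`` (default 1.3, the shallow-divergence regime
  typical of short repeat alignments)

NJ is the standard Q-criterion agglomeration with deterministic
lexicographic tie-breaks; negative branch lengths are clamped to zero with
the deficit moved to the sibling branch so path lengths are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .seqio import Alignment


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DistanceError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DistanceError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise DistanceError("distances must be finite and non-negative")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# taxa\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in self.d[i]) + "\n")


def _codes_distance(codes: np.ndarray, taxa: list[str], model: str,
                    gamma_alpha: float) -> DistanceMatrix:
    n = codes.shape[0]
    ok = (codes >= 0) & (codes < 20)        # X treated as missing
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise DistanceError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}")
            p = float((codes[i, both] != codes[j, both]).sum()) / m
            if model == "p":
                dist = p
            elif model == "poisson":
                if p >= 1.0:
                    raise DistanceError(
                        f"p=1 between {taxa[i]!r} and {taxa[j]!r}: "
                        "Poisson correction undefined")
                dist = -math.log(1.0 - p)
            elif model == "gamma":
                if p >= 1.0:
                    raise DistanceError(
                        f"p=1 between {taxa[i]!r} and {taxa[j]!r}: "
                        "gamma correction undefined")
                a = gamma_alpha
                dist = a * ((1.0 - p) ** (-1.0 / a) - 1.0)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=list(taxa), d=d)


def pairwise_distance(aln: Alignment, model: str = "gamma",
                      gamma_alpha: float = 1.3) -> DistanceMatrix:
    """Pairwise-deletion distances between alignment rows."""
    if len(aln) < 2:
        raise DistanceError("need at least two rows")
    return _codes_distance(aln.codes(), aln.ids, model, gamma_alpha)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; root trifurcation by convention).

    Tie-breaks in the Q minimum are by the lexicographic pair of cluster
    keys (a cluster's key is its smallest leaf label).  Negative branch
    lengths are clamped to 0 and the deficit added to the sibling.
    """
    n = len(dm.taxa)
    if n < 3:
        raise DistanceError("NJ needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes = []
    for t in dm.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(t))
        nodes.append({"key": t, "node": nd})
    D = dm.d.copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i]["key"], nodes[j]["key"])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i]["node"])
        nodes[i]["node"].edge.length = li
        parent.add_child(nodes[j]["node"])
        nodes[j]["node"].edge.length = lj
        new_key = min(nodes[i]["key"], nodes[j]["key"])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        nodes = [nodes[x] for x in keep] + [{"key": new_key, "node": parent}]
        D = D2

    # final star join of the remaining three clusters
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = dendropy.Node()
    for nd, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nd["node"])
        nd["node"].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------

def _leaf_paths(tree: dendropy.Tree):
    """All leaf pairs with path length and the path's edge list."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    parent = {}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            parent[ch] = nd

    def ancestors(nd):
        chain = [(nd, 0.0)]
        dist = 0.0
        while nd in parent:
            dist += nd.edge.length or 0.0
            nd = parent[nd]
            chain.append((nd, dist))
        return chain

    anc = {l: ancestors(l) for l in leaves}
    for i, u in enumerate(leaves):
        au = {nd: dd for nd, dd in anc[u]}
        for v in leaves[i + 1:]:
            for nd, dv in anc[v]:
                if nd in au:
                    yield u, v, au[nd] + dv, nd
                    break


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root.  Ties in the
    longest path are broken by the lexicographic leaf-label pair.
    """
    tree = tree.clone(depth=1)
    best = None
    for u, v, dist, _mrca in _leaf_paths(tree):
        key = (-dist, u.taxon.label, v.taxon.label)
        if best is None or key < best[0]:
            best = (key, u, v, dist)
    if best is None:
        raise DistanceError("tree has fewer than two leaves")
    _, u, v, dmax = best
    if dmax <= 0:
        raise DistanceError("cannot midpoint-root a tree with all-zero branch lengths")
    half = dmax / 2.0

    # walk from u toward v until the midpoint edge
    parent = {}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            parent[ch] = nd
    chain_u = []
    nd = u
    while nd in parent:
        chain_u.append(nd)
        nd = parent[nd]
    chain_u.append(nd)
    set_u = {x: i for i, x in enumerate(chain_u)}
    chain_v = []
    nd = v
    while nd not in set_u:
        chain_v.append(nd)
        nd = parent[nd]
    mrca = nd
    path_nodes = chain_u[:set_u[mrca] + 1] + list(reversed(chain_v))
    # edges along the path: between consecutive nodes, child side carries length
    acc = 0.0
    for a, b in zip(path_nodes[:-1], path_nodes[1:]):
        child = a if parent.get(a) is b else b
        elen = child.edge.length or 0.0
        if acc + elen >= half - 1e-15:
            offset = half - acc          # measured from the 'a' end of the edge
            if parent.get(a) is b:       # walking child -> parent
                l_child = offset
                l_parent = elen - offset
            else:                        # walking parent -> child
                l_child = elen - offset
                l_parent = offset
            tree.reroot_at_edge(child.edge, length1=l_parent, length2=l_child,
                                update_bipartitions=False)
            tree.is_rooted = True
            # dendropy's length1/length2 orientation varies; enforce equidistance
            _fix_root_balance(tree, u.taxon.label, v.taxon.label, half)
            return tree
        acc += elen
    raise DistanceError("midpoint not found on path (inconsistent branch lengths)")


def _fix_root_balance(tree: dendropy.Tree, lu: str, lv: str, half: float) -> None:
    def depth_of(label):
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == label:
                d, nd = 0.0, leaf
                while nd.parent_node is not None:
                    d += nd.edge.length or 0.0
                    nd = nd.parent_node
                return d
        raise KeyError(label)

    du = depth_of(lu)
    kids = tree.seed_node.child_nodes()
    if abs(du - half) > 1e-9 and len(kids) == 2:
        e0, e1 = kids[0].edge.length or 0.0, kids[1].edge.length or 0.0
        total = e0 + e1
        delta = du - half
        # slide the root along its two child edges until leaf lu sits at half
        sub0 = {l.taxon.label for l in kids[0].leaf_iter()}
        if lu in sub0:
            kids[0].edge.length = max(e0 - delta, 0.0)
            kids[1].edge.length = max(total - max(e0 - delta, 0.0), 0.0)
        else:
            kids[1].edge.length = max(e1 - delta, 0.0)
            kids[0].edge.length = max(total - max(e1 - delta, 0.0), 0.0)


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits, each encoded as the leaf side not containing the
    lexicographically smallest taxon."""
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    ref = min(all_leaves)
    out = set()
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if ref in side:
            side = frozenset(all_leaves - side)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def bootstrap_support(aln: Alignment, model: str = "gamma", n_boot: int = 100,
                      seed: int = 0, gamma_alpha: float = 1.3) -> dendropy.Tree:
    """NJ tree with bootstrap percentages on internal nodes.

    Columns are resampled with replacement per replicate (seeded); support of
    each bipartition of the point-estimate tree is the percentage of
    replicate NJ trees containing it.  The point tree itself does not depend
    on the seed.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10")
    codes = aln.codes()
    point = nj_tree(pairwise_distance(aln, model, gamma_alpha))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(point)}
    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        try:
            dm = _codes_distance(codes[:, cols], aln.ids, model, gamma_alpha)
        except DistanceError:
            continue    # replicate with an incomparable pair is skipped
        for bp in _bipartitions(nj_tree(dm)):
            if bp in counts:
                counts[bp] += 1
    all_leaves = {l.taxon.label for l in point.leaf_node_iter()}
    ref = min(all_leaves)
    for nd in point.preorder_internal_node_iter():
        if nd is point.seed_node:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if ref in side:
            side = frozenset(all_leaves - side)
        if side in counts:
            nd.label = str(int(round(100.0 * counts[side] / n_boot)))
    return point


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick",
                                real_value_format_specifier=".6f",
                                suppress_rooting=True))


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
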