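import itertools
import math

import numpy as np
import pytest

from taumap.phylo_lite import (DistanceError, DistanceMatrix, _bipartitions,
                               bootstrap_support, midpoint_root, nj_tree,
                               pairwise_distance, read_tree, write_tree)
from taumap.seqio import Alignment, SequenceRecord


def make_aln(rows):
    return Alignment([SequenceRecord(f"t{i}", r) for i, r in enumerate(rows)])


# ---------------------------------------------------------------------------
# oracle helpers
# ---------------------------------------------------------------------------

def five_taxon_topologies():
    """All 15 unrooted leaf-labelled topologies on taxa 0..4, as split pairs."""
    taxa = list(range(5))
    seen = []
    for pair1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            key = frozenset([frozenset(pair1), frozenset(pair2)])
            if key not in seen:
                seen.append(key)
    assert len(seen) == 15
    return seen


def topology_splits(key):
    return {frozenset(s) for s in key}


def random_additive_matrix(rng):
    """Random 5-taxon tree metric; returns (D, its two non-trivial splits)."""
    key = five_taxon_topologies()[int(rng.integers(0, 15))]
    (a, b), (c, d) = [tuple(sorted(s)) for s in key]
    e = next(t for t in range(5) if t not in (a, b, c, d))
    # tree: ((a,b)u, (c,d)v, e) with internal edges u-w, v-w
    bl = {t: rng.uniform(0.05, 1.0) for t in range(5)}
    iu, iv = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
    D = np.zeros((5, 5))

    def path(x, y):
        if {x, y} == {a, b}:
            return bl[x] + bl[y]
        if {x, y} == {c, d}:
            return bl[x] + bl[y]
        px = iu if x in (a, b) else (iv if x in (c, d) else 0.0)
        py = iu if y in (a, b) else (iv if y in (c, d) else 0.0)
        return bl[x] + px + bl[y] + py

    for x in range(5):
        for y in range(x + 1, 5):
            D[x, y] = D[y, x] = path(x, y)
    return D, key


def fit_topology_least_squares(D, key):
    """Exact least-squares branch fit of D on a topology; returns residual."""
    (a, b), (c, d) = [tuple(sorted(s)) for s in key]
    e = next(t for t in range(5) if t not in (a, b, c, d))
    # unknowns: 5 leaf branches + 2 internal edges
    cols = {("leaf", t): i for i, t in enumerate(range(5))}
    cols[("int", "u")] = 5
    cols[("int", "v")] = 6
    rows, rhs = [], []
    for x in range(5):
        for y in range(x + 1, 5):
            r = np.zeros(7)
            r[cols[("leaf", x)]] = 1
            r[cols[("leaf", y)]] = 1
            if (x in (a, b)) != (y in (a, b)):
                r[cols[("int", "u")]] = 1 if (x in (a, b)) or (y in (a, b)) else 0
            if (x in (c, d)) != (y in (c, d)):
                r[cols[("int", "v")]] = 1 if (x in (c, d)) or (y in (c, d)) else 0
            rows.append(r)
            rhs.append(D[x, y])
    A = np.array(rows)
    sol, *_ = np.linalg.lstsq(A, np.array(rhs), rcond=None)
    return float(np.abs(A @ sol - rhs).max())


def exhaustive_best_topology(D):
    fits = [(fit_topology_least_squares(D, key), i)
            for i, key in enumerate(five_taxon_topologies())]
    fits.sort()
    return five_taxon_topologies()[fits[0][1]], fits[0][0]


def tree_splits(tree):
    return _bipartitions(tree)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_identical_rows_zero_under_all_models(self):
        aln = make_aln(["ACDEF", "ACDEF"])
        for model in ("p", "poisson", "gamma"):
            assert pairwise_distance(aln, model).d[0, 1] == 0.0

    def test_poisson_half_mismatch(self):
        aln = make_aln(["AAAA", "AACC"])
        d = pairwise_distance(aln, "poisson").d[0, 1]
        assert d == pytest.approx(-math.log(0.5), abs=1e-4)   # 0.6931

    def test_gamma_half_mismatch_alpha_1_3(self):
        aln = make_aln(["AAAA", "AACC"])
        d = pairwise_distance(aln, "gamma", gamma_alpha=1.3).d[0, 1]
        assert d == pytest.approx(1.3 * (0.5 ** (-1 / 1.3) - 1), abs=1e-6)
        assert d == pytest.approx(0.9157, abs=1e-3)

    def test_pairwise_deletion_uses_shared_columns_only(self):
        aln = make_aln(["AC--", "--CA", "ACCA"])
        with pytest.raises(DistanceError, match="t0.*t1|t1.*t0"):
            pairwise_distance(aln, "p")

    def test_saturated_pair_rejected_for_poisson(self):
        aln = make_aln(["AAAA", "CCCC"])
        with pytest.raises(DistanceError, match="undefined"):
            pairwise_distance(aln, "poisson")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                           "C": pytest.approx(2.0)}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(DistanceError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))

    def test_additive_matrices_recover_generating_topology(self, rng):
        """NJ agrees with exhaustive least-squares search over all 15
        unrooted 5-taxon topologies on additive matrices."""
        for _ in range(10):
            D, key = random_additive_matrix(rng)
            best_key, resid = exhaustive_best_topology(D)
            assert best_key == key and resid < 1e-9
            dm = DistanceMatrix([f"t{i}" for i in range(5)], D)
            got = tree_splits(nj_tree(dm))
            want = {frozenset(f"t{i}" for i in s) for s in topology_splits(key)}
            norm_want = set()
            ref = "t0"
            allt = {f"t{i}" for i in range(5)}
            for s in want:
                norm_want.add(frozenset(allt - s) if ref in s else s)
            assert got == norm_want

    def test_additive_matrix_path_lengths_reproduced(self, rng):
        D, _ = random_additive_matrix(rng)
        dm = DistanceMatrix([f"t{i}" for i in range(5)], D)
        tree = nj_tree(dm)
        pdm = {}
        for u in tree.leaf_node_iter():
            for v in tree.leaf_node_iter():
                if u.taxon.label < v.taxon.label:
                    pdm[(u.taxon.label, v.taxon.label)] = None
        # path lengths via dendropy
        pd = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        for i in range(5):
            for j in range(i + 1, 5):
                got = pd.distance(tns.get_taxon(f"t{i}"), tns.get_taxon(f"t{j}"))
                assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_scikit_bio_on_random_matrices(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj
        for _ in range(5):
            n = 6
            M = rng.uniform(0.1, 1.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            taxa = [f"t{i}" for i in range(n)]
            ours = tree_splits(nj_tree(DistanceMatrix(taxa, D)))
            sk_tree = sknj(SkDM(D, ids=taxa))
            ref = min(taxa)
            theirs = set()
            allt = set(taxa)
            for node in sk_tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = frozenset(allt - side)
                if 1 < len(side) < n - 1:
                    theirs.add(side)
            assert ours == theirs


# ---------------------------------------------------------------------------
# rooting and bootstrap
# ---------------------------------------------------------------------------

class TestMidpoint:
    def test_symmetric_quartet_roots_on_central_branch(self):
        D = np.array([[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0.0]])
        tree = midpoint_root(nj_tree(DistanceMatrix(list("ABCD"), D)))
        depths = {}
        for leaf in tree.leaf_node_iter():
            d, nd = 0.0, leaf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths[leaf.taxon.label] = d
        assert depths["A"] == pytest.approx(2.5, abs=1e-9)
        assert depths["C"] == pytest.approx(2.5, abs=1e-9)

    def test_three_taxon_midpoint_halves_longest_path(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
        tree = midpoint_root(nj_tree(dm))
        depths = {}
        for leaf in tree.leaf_node_iter():
            d, nd = 0.0, leaf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths[leaf.taxon.label] = d
        # longest path B..C has length 3 -> both 1.5 from the root
        assert depths["B"] == pytest.approx(1.5, abs=1e-9)
        assert depths["C"] == pytest.approx(1.5, abs=1e-9)

    def test_idempotent(self):
        D = np.array([[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0.0]])
        t1 = midpoint_root(nj_tree(DistanceMatrix(list("ABCD"), D)))
        t2 = midpoint_root(t1)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_all_zero_branch_lengths_rejected(self):
        dm = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        with pytest.raises(DistanceError):
            midpoint_root(nj_tree(dm))


class TestBootstrap:
    def _clean_alignment(self):
        # zero homoplasy: each taxon group has its own diagnostic residues
        blocks = {"A": "AAAA", "B": "AAAC", "C": "GGGG", "D": "GGGC",
                  "E": "WWWW", "F": "WWWC"}
        rows = []
        for name, motif in blocks.items():
            rows.append(motif * 8)
        return Alignment([SequenceRecord(k, blocks[k] * 8) for k in blocks])

    def test_unanimous_support_without_homoplasy(self):
        tree = bootstrap_support(self._clean_alignment(), model="p",
                                 n_boot=50, seed=4)
        sups = [int(nd.label) for nd in tree.preorder_internal_node_iter()
                if nd.label is not None]
        assert sups and all(s == 100 for s in sups)

    def test_same_seed_identical_supports(self, default_family):
        aln = default_family.repeat_alignment
        sub = Alignment(aln.records[:20])
        t1 = bootstrap_support(sub, n_boot=30, seed=9)
        t2 = bootstrap_support(sub, n_boot=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_point_tree_independent_of_seed(self, default_family):
        sub = Alignment(default_family.repeat_alignment.records[:15])
        t1 = bootstrap_support(sub, n_boot=20, seed=1)
        t2 = bootstrap_support(sub, n_boot=20, seed=2)
        assert tree_splits(t1) == tree_splits(t2)

    def test_supports_within_bounds(self, default_family):
        sub = Alignment(default_family.repeat_alignment.records[:15])
        tree = bootstrap_support(sub, n_boot=20, seed=3)
        for nd in tree.preorder_internal_node_iter():
            if nd.label is not None:
                assert 0 <= int(nd.label) <= 100

    def test_paralog_clades_monophyletic_with_support(self):
        """The three paralog clades of the simulated family are recovered
        monophyletic with bootstrap support >= 70 (seed 11)."""
        from taumap.synthetic_data import map_family_default, simulate_family
        fam = simulate_family(map_family_default(n_species=12, divergence=0.2,
                                                 seed=11))
        tree = bootstrap_support(fam.alignment, "gamma", n_boot=100, seed=11)
        alll = {l.taxon.label for l in tree.leaf_node_iter()}
        for paralog in ("MAPT", "MAP2", "MAP4"):
            clade = frozenset(x for x in alll if x.endswith("|" + paralog))
            sup = None
            for nd in tree.preorder_internal_node_iter():
                s = frozenset(l.taxon.label for l in nd.leaf_iter())
                if s == clade or (alll - s) == clade:
                    sup = int(nd.label)
            assert sup is not None and sup >= 70


class TestNewickIO:
    def test_roundtrip(self, tmp_path, default_family):
        sub = Alignment(default_family.repeat_alignment.records[:10])
        tree = nj_tree(pairwise_distance(sub, "p"))
        p = tmp_path / "t.nwk"
        write_tree(tree, p)
        back = read_tree(p)
        assert tree_splits(back) == tree_splits(tree)
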