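"""TN93 distances, neighbor joining, bootstrap, lineage assignment."""

import math

import numpy as np
import pytest

from kirdiv.phylo import (
    DistanceMatrix,
    PhyloTree,
    assign_lineage,
    bootstrap_support,
    distance_matrix,
    nj_build,
    tn93_distance,
)
from kirdiv.synthetic_data import _coalescent_tree, simulate_lineage_panel


def tn93_oracle(a: str, b: str) -> float:
    """Independent closed-form TN93 evaluation (kept free of the library path)."""
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    from collections import Counter

    base = Counter()
    for x, y in pairs:
        base[x] += 1
        base[y] += 1
    g = {k: base[k] / (2 * n) for k in "ACGT"}
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    P1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    Q = sum(1 for x, y in pairs if x != y and ({x, y} not in ({"A", "G"}, {"C", "T"}))) / n
    k1 = 2 * g["A"] * g["G"] / gR
    k2 = 2 * g["C"] * g["T"] / gY
    d = 0.0
    if k1:
        d -= k1 * math.log(1 - P1 / k1 - Q / (2 * gR))
    if k2:
        d -= k2 * math.log(1 - P2 / k2 - Q / (2 * gY))
    d -= (
        2
        * (gR * gY - g["A"] * g["G"] * gY / gR - g["C"] * g["T"] * gR / gY)
        * math.log(1 - Q / (2 * gR * gY))
    )
    return d


def random_additive_case(n, rng):
    """A random tree and its exact path-length matrix."""
    t = _coalescent_tree(n, rng)
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length = rng.uniform(0.1, 1.0)
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    names = [x.label for x in taxa]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
    return names, m


class TestTN93:
    def test_identity_is_zero(self):
        a = "ACGT" * 75
        assert tn93_distance(a, a) == (0.0, 300)

    def test_single_transversion_matches_closed_form(self):
        a = "ACGT" * 75
        b = "C" + a[1:]
        d, n = tn93_distance(a, b)
        assert n == 300
        assert d == pytest.approx(tn93_oracle(a, b), abs=1e-12)

    def test_mixed_changes_match_closed_form(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), size=600, p=[0.3, 0.2, 0.3, 0.2]))
        b = list(a)
        for i in rng.choice(600, size=50, replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
        b = "".join(b)
        d, _ = tn93_distance(a, b)
        assert d == pytest.approx(tn93_oracle(a, b), abs=1e-12)

    def test_pairwise_deletion_site_count(self):
        a = "ACGT" * 75
        c = "-" * 10 + a[10:]
        _, n = tn93_distance(a, c)
        assert n == 290

    def test_equals_jukes_cantor_in_symmetric_limit(self):
        # equal base frequencies and equal counts of every change type
        blocks = []
        for x in "ACGT":
            blocks.append((x, x) * 25)
        diffs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
                 ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
        a = "".join(x * 25 for x in "ACGT") + "".join(x for x, _ in diffs)
        b = "".join(x * 25 for x in "ACGT") + "".join(y for _, y in diffs)
        d, n = tn93_distance(a, b)
        p = 12 / n
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert d == pytest.approx(jc, abs=1e-9)

    def test_saturation_flagged_not_propagated(self):
        a = "A" * 50 + "C" * 50
        b = "C" * 50 + "A" * 50
        d, n = tn93_distance(a, b)
        assert math.isnan(d) and n == 100

    def test_all_gapped_inapplicable(self):
        d, n = tn93_distance("----", "ACGT")
        assert math.isnan(d) and n == 0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        names = ["a", "b", "c"]
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_build(DistanceMatrix(names=names, matrix=m))
        pl = tree.path_length_matrix(names)
        assert np.allclose(pl, m, atol=1e-12)

    def test_additive_matrices_recovered(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            names, m = random_additive_case(n, rng)
            tree = nj_build(DistanceMatrix(names=names, matrix=m))
            assert np.allclose(tree.path_length_matrix(names), m, atol=1e-9)

    def test_matches_scikit_bio_topology(self):
        import skbio

        rng = np.random.default_rng(3)
        names, m = random_additive_case(8, rng)
        mine = nj_build(DistanceMatrix(names=names, matrix=m))
        sk = skbio.tree.nj(skbio.DistanceMatrix(m, ids=names))
        import dendropy

        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine.newick(), schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(sk).strip(), schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_tie_rule_is_deterministic(self):
        names = list("abcd")
        m = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        t1 = nj_build(DistanceMatrix(names=names, matrix=m)).newick()
        t2 = nj_build(DistanceMatrix(names=names, matrix=m)).newick()
        assert t1 == t2

    def test_inapplicable_entries_name_taxa(self):
        m = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(ValueError, match="remove affected taxa"):
            nj_build(DistanceMatrix(names=list("abc"), matrix=m))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            nj_build(DistanceMatrix(names=["a", "b"], matrix=np.zeros((2, 2))))

    def test_negative_branch_lengths_clamped_only_in_newick(self):
        names = list("abcd")
        m = np.array(
            [[0, 0.1, 0.4, 0.45], [0.1, 0, 0.45, 0.4], [0.4, 0.45, 0, 0.1],
             [0.45, 0.4, 0.1, 0]]
        )
        tree = nj_build(DistanceMatrix(names=names, matrix=m))
        assert "-" not in tree.newick().replace("e-", "")


class TestBootstrap:
    @pytest.fixture
    def separated_alignment(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(list("ACGT"), size=300))
        other = list(core)
        for i in rng.choice(300, size=90, replace=False):
            other[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[core[i]]
        other = "".join(other)

        def jitter(s, k, rng):
            s = list(s)
            for i in rng.choice(len(s), size=k, replace=False):
                s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
            return "".join(s)

        return {
            "a1": core, "a2": jitter(core, 2, rng),
            "b1": other, "b2": jitter(other, 2, rng),
        }

    def test_clear_split_has_high_support(self, separated_alignment):
        tree = bootstrap_support(separated_alignment, reps=100, seed=1)
        labels = [
            float(n.label)
            for n in tree.tree.preorder_internal_node_iter()
            if n.label is not None
        ]
        assert labels and max(labels) >= 95

    def test_single_rep_supports_degenerate(self, separated_alignment):
        tree = bootstrap_support(separated_alignment, reps=1, seed=1)
        labels = {
            float(n.label)
            for n in tree.tree.preorder_internal_node_iter()
            if n.label is not None
        }
        assert labels <= {0.0, 100.0}

    def test_reps_below_one_rejected(self, separated_alignment):
        with pytest.raises(ValueError):
            bootstrap_support(separated_alignment, reps=0)

    def test_identical_sequences_flagged_arbitrary(self):
        aln = {f"t{i}": "ACGT" * 30 for i in range(4)}
        tree = bootstrap_support(aln, reps=5, seed=1)
        assert tree.arbitrary_topology

    def test_support_invariant_to_taxon_order(self, separated_alignment):
        items = list(separated_alignment.items())
        t1 = bootstrap_support(dict(items), reps=50, seed=9)
        t2 = bootstrap_support(dict(reversed(items)), reps=50, seed=9)
        assert t1.newick() == t2.newick()


class TestLineageAssignment:
    def test_identical_query_gets_reference_lineage(self):
        q, refs, labels, _ = simulate_lineage_panel(seed=0, n_lineages=3)
        rname = next(n for n, l in labels.items() if l == "II")
        res = assign_lineage({"q0": refs[rname]}, refs, labels, reps=50, seed=1)
        assert res[0].lineage == "II"
        assert res[0].support >= 70

    def test_within_clade_queries_recovered(self):
        correct = total = 0
        for seed in range(4):
            q, refs, labels, truth = simulate_lineage_panel(seed=seed)
            for a in assign_lineage(q, refs, labels, reps=100, seed=seed):
                total += 1
                correct += a.lineage == truth[a.query]
        assert correct / total >= 0.95

    def test_ambiguous_query_unresolved(self):
        # query maximally distant from two tight clusters
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=240))
        far = "".join(
            {"A": "G", "G": "A", "C": "T", "T": "C"}[c] if i % 4 == 0 else c
            for i, c in enumerate(base)
        )
        refs = {"r1": base, "r2": base, "r3": far, "r4": far}
        labels = {"r1": "I", "r2": "I", "r3": "II", "r4": "II"}
        mid = list(base)
        for i in range(0, 240, 8):
            mid[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mid[i]]
        res = assign_lineage({"q": "".join(mid)}, refs, labels,
                             support_threshold=70, reps=50, seed=1)
        # the query either resolves with real support or is reported unresolved
        assert res[0].lineage in {"I", "II", "unresolved"}
        if res[0].lineage == "unresolved":
            assert res[0].support == 0.0

    def test_singleton_lineage_warns(self):
        q, refs, labels, _ = simulate_lineage_panel(seed=1, n_lineages=2)
        one = next(n for n, l in labels.items() if l == "II")
        small_refs = {n: s for n, s in refs.items() if labels[n] == "I" or n == one}
        small_labels = {n: labels[n] for n in small_refs}
        with pytest.warns(UserWarning, match="<2 members"):
            assign_lineage({"q": small_refs[one]}, small_refs, small_labels,
                           reps=20, seed=1)
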