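"""Distances, NJ, UPGMA, and bootstrap supports, checked against
independent oracles (brute-force least squares, naive average linkage,
scikit-bio's NJ)."""

import numpy as np
import pytest

from rhodofit.phylogeny import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
    tree_splits,
    upgma,
    write_newick,
)
from rhodofit.simulate import simulate_alignment

from conftest import seven_taxon_tree


# ---------------------------------------------------------------------------
# helpers


def random_additive_tree(labels, rng):
    """Random binary tree: returns (distance matrix, set of nontrivial
    bipartitions), with distances exactly additive on the tree."""
    labels = list(labels)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    dist = np.zeros((n, n))
    clusters = [({lab}, {lab: 0.0}) for lab in labels]
    clades = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        (si, di), (sj, dj) = clusters[i], clusters[j]
        li, lj = rng.uniform(0.05, 1.0, 2)
        for a, da in di.items():
            for b, db in dj.items():
                dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = da + li + db + lj
        merged = si | sj
        newd = {k: v + li for k, v in di.items()}
        newd.update({k: v + lj for k, v in dj.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, newd))
        if len(clusters) > 1:
            clades.append(frozenset(merged))
    all_set = frozenset(labels)
    splits = {
        frozenset({c, all_set - c})
        for c in clades
        if 2 <= len(c) <= n - 2
    }
    return DistanceMatrix(labels, dist), splits


def leaf_edge_lengths(tree):
    return {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}


def cophenetic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], m


# ---------------------------------------------------------------------------
# p-distances


class TestPDistance:
    def test_basic_values(self):
        aln = Alignment(("a", "b", "c"), ("ACGT", "ACGA", "TGCA"))
        d = p_distance_matrix(aln)
        assert d.matrix[0, 0] == 0.0
        assert d.matrix[0, 1] == pytest.approx(0.25)
        assert d.matrix[0, 2] == pytest.approx(1.0)

    def test_gap_exclusion(self):
        aln = Alignment(("a", "b"), ("AC-T", "ACG-"))
        # only columns 1-2 are comparable; both identical
        assert p_distance_matrix(aln).matrix[0, 1] == 0.0

    def test_no_comparable_columns_error(self):
        aln = Alignment(("a", "b"), ("A--", "-AA"))
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix(aln)

    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = DistanceMatrix(("a", "b", "c"), np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]))
        tree = neighbor_joining(d)
        lengths = leaf_edge_lengths(tree)
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_size_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]])))

    def test_quartet_against_least_squares_brute_force(self, rng):
        labels = ["A", "B", "C", "D"]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        # topology -> the two sister pairs; branch order (a,b,c,d,internal)
        topologies = {
            frozenset({frozenset("AB"), frozenset("CD")}): [(0, 1), (2, 3)],
            frozenset({frozenset("AC"), frozenset("BD")}): [(0, 2), (1, 3)],
            frozenset({frozenset("AD"), frozenset("BC")}): [(0, 3), (1, 2)],
        }

        def design(sisters):
            rows = []
            for (i, j) in pairs:
                row = np.zeros(5)
                row[i] += 1
                row[j] += 1
                (s1, s2) = sisters
                if not ((i in s1 and j in s1) or (i in s2 and j in s2)):
                    row[4] = 1  # crosses the internal edge
                rows.append(row)
            return np.array(rows)

        for _ in range(10):
            d, true_splits = random_additive_tree(labels, rng)
            y = np.array([d.matrix[i, j] for (i, j) in pairs])
            scores = {}
            for split, sisters in topologies.items():
                X = design(sisters)
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                scores[split] = float(np.sum((X @ coef - y) ** 2))
            brute_best = min(scores, key=scores.get)
            nj_splits = set(tree_splits(neighbor_joining(d), rooted=False).values())
            assert nj_splits == {brute_best} == true_splits

    @pytest.mark.parametrize("n", [6, 8])
    def test_additive_recovery_topology_and_path_lengths(self, rng, n):
        labels = [f"T{i}" for i in range(n)]
        for _ in range(5):
            d, true_splits = random_additive_tree(labels, rng)
            tree = neighbor_joining(d)
            assert set(tree_splits(tree, rooted=False).values()) == true_splits
            labs, coph = cophenetic(tree)
            order = [labels.index(l) for l in labs]
            assert np.allclose(coph, d.matrix[np.ix_(order, order)], atol=1e-9)

    def test_agrees_with_scikit_bio_nj(self, rng):
        import skbio

        labels = [f"T{i}" for i in range(6)]
        for _ in range(5):
            d, _ = random_additive_tree(labels, rng)
            noisy = d.matrix + rng.uniform(0, 0.01, d.matrix.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            dm = DistanceMatrix(labels, noisy)
            mine = set(tree_splits(neighbor_joining(dm), rooted=False).values())
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, labels))
            all_set = frozenset(labels)
            theirs = set()
            for node in sk_tree.non_tips(include_self=False):
                below = frozenset(t.name for t in node.tips())
                other = all_set - below
                if len(below) >= 2 and len(other) >= 2:
                    theirs.add(frozenset({below, other}))
            assert mine == theirs


# ---------------------------------------------------------------------------
# UPGMA


class TestUpgma:
    def test_two_taxa_root_height(self):
        d = DistanceMatrix(("a", "b"), np.array([[0, 0.8], [0.8, 0]]))
        tree = upgma(d)
        lengths = leaf_edge_lengths(tree)
        assert lengths["a"] == pytest.approx(0.4)
        assert lengths["b"] == pytest.approx(0.4)

    def test_output_always_ultrametric(self, rng):
        for _ in range(5):
            m = rng.uniform(0.1, 1.0, (6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = upgma(DistanceMatrix([f"T{i}" for i in range(6)], m))
            depths = []
            for lf in tree.leaf_node_iter():
                depth, node = 0.0, lf
                while node.parent_node is not None:
                    depth += node.edge.length
                    node = node.parent_node
                depths.append(depth)
            assert np.allclose(depths, depths[0], atol=1e-9)

    def test_matches_naive_average_linkage_oracle(self, rng):
        # naive O(n^3) oracle: merge heights from averages over ORIGINAL
        # pairwise distances, cophenetic distance = 2 x merge height
        labels = [f"T{i}" for i in range(6)]
        for _ in range(5):
            m = rng.uniform(0.1, 1.0, (6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            clusters = [[i] for i in range(6)]
            coph = np.zeros((6, 6))
            while len(clusters) > 1:
                best = None
                for a in range(len(clusters)):
                    for b in range(a + 1, len(clusters)):
                        avg = np.mean([m[x, y] for x in clusters[a] for y in clusters[b]])
                        if best is None or avg < best[0]:
                            best = (avg, a, b)
                avg, a, b = best
                for x in clusters[a]:
                    for y in clusters[b]:
                        coph[x, y] = coph[y, x] = avg
                clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
                    clusters[a] + clusters[b]
                ]
            tree = upgma(DistanceMatrix(labels, m))
            labs, mine = cophenetic(tree)
            order = [labels.index(l) for l in labs]
            assert np.allclose(mine, coph[np.ix_(order, order)], atol=1e-9)


# ---------------------------------------------------------------------------
# bootstrap


def support_map(tree, rooted):
    return {
        split: int(node.label)
        for node, split in tree_splits(tree, rooted).items()
        if node.label is not None
    }


class TestBootstrap:
    def test_clean_alignment_fully_supported_both_methods(self, clean_tree):
        aln = simulate_alignment(clean_tree, 1000, seed=1)
        for method in ("nj", "upgma"):
            tree = bootstrap_support(aln, method=method, replicates=100, seed=2)
            supports = support_map(tree, rooted=(method == "upgma"))
            assert supports, "expected internal nodes with supports"
            assert all(s == 100 for s in supports.values())

    def test_replicates_validation(self, clean_tree):
        aln = simulate_alignment(clean_tree, 100, seed=1)
        with pytest.raises(ValueError):
            bootstrap_support(aln, replicates=0, seed=1)
        with pytest.raises(ValueError, match="outgroup"):
            bootstrap_support(aln, replicates=5, seed=1, outgroup="nope")

    def test_seed_reproducibility(self, clean_tree):
        aln = simulate_alignment(clean_tree, 300, seed=4)
        t1 = bootstrap_support(aln, method="nj", replicates=20, seed=11)
        t2 = bootstrap_support(aln, method="nj", replicates=20, seed=11)
        assert support_map(t1, False) == support_map(t2, False)

    def test_taxon_order_permutation_invariance(self, clean_tree, rng):
        aln = simulate_alignment(clean_tree, 400, seed=6)
        perm = rng.permutation(aln.n_taxa)
        shuffled = Alignment(
            tuple(aln.names[i] for i in perm), tuple(aln.rows[i] for i in perm)
        )
        s1 = support_map(bootstrap_support(aln, "nj", 25, seed=3), False)
        s2 = support_map(bootstrap_support(shuffled, "nj", 25, seed=3), False)
        assert s1 == s2

    def test_outgroup_rooting_preserves_supports(self, clean_tree):
        aln = simulate_alignment(clean_tree, 800, seed=5)
        rooted = bootstrap_support(aln, "nj", 25, seed=8, outgroup="G")
        children = rooted.seed_node.child_nodes()
        assert any(
            ch.is_leaf() and ch.taxon.label == "G" for ch in children
        )
        # splits and their supports survive the rerooting
        assert all(v == 100 for v in support_map(rooted, False).values())


def test_newick_output_round_trips(tmp_path, clean_tree):
    import dendropy

    aln = simulate_alignment(clean_tree, 500, seed=1)
    tree = bootstrap_support(aln, "nj", 10, seed=1)
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    back = dendropy.Tree.get(path=str(path), schema="newick")
    assert {lf.taxon.label for lf in back.leaf_node_iter()} == set(aln.names)
    text = path.read_text()
    assert ":" in text and "100" in text


def test_fasta_round_trip(tmp_path):
    aln = simulate_alignment(seven_taxon_tree(), 60, seed=2)
    path = tmp_path / "aln.fasta"
    aln.to_fasta(path)
    back = Alignment.from_fasta(path)
    assert back == aln
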