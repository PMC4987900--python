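import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage

from confstats.alignment import align_by_numbering
from confstats.clustering import (DistanceMatrix, cut_tree,
                                  emit_cluster_families, linkage_complete,
                                  structure_distance, to_newick, cluster)
from confstats.io import (EnsembleError, PositionSelection,
                          parse_structure_list)
from confstats.torsions import all_torsions
from conftest import two_family_ensemble


def matrix_from_full(full, labels=None):
    n = full.shape[0]
    labels = labels or [f"s{i}" for i in range(n)]
    cond = [full[i, j] for i in range(n) for j in range(i + 1, n)]
    return DistanceMatrix(labels=labels, values=np.array(cond),
                          n_variables_used=[1] * len(cond))


def random_distance_matrix(seed, n=8):
    rng = np.random.default_rng(seed)
    full = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    # distinct values so the scipy comparison is tie-free
    vals = rng.permutation(len(iu[0])) * 1.37 + rng.uniform(0, 1, len(iu[0])) * 0.1
    full[iu] = vals
    full += full.T
    return matrix_from_full(full)


class TestStructureDistance:
    def _setup(self, ensemble):
        structures, _ = ensemble
        align = align_by_numbering(structures)
        maps = {s.label: {(r.residue_index, r.angle): r.value
                          for r in all_torsions(s) if r.value is not None}
                for s in structures}
        return structures, align, maps

    def test_identical_torsions_give_zero(self, ensemble2fam):
        structures, align, maps = self._setup(ensemble2fam)
        lab = structures[0].label
        sel = PositionSelection()
        d, n = structure_distance(maps[lab], maps[lab], sel, align, lab, lab)
        assert d == 0.0 and n > 0

    def test_single_variable_is_its_circ_dist(self):
        t1, t2 = {(0, "phi"): 0.0}, {(0, "phi"): 120.0}

        class FakeAlign:
            first_position = 1
            n_columns = 1
            structures = ["a", "b"]
            cells = {"a": [0], "b": [0]}
            positions = range(1, 2)

            def column_of(self, p):
                return p - 1

        sel = PositionSelection(angles={"phi"})
        d, n = structure_distance(t1, t2, sel, FakeAlign(), "a", "b")
        assert d == pytest.approx(120.0) and n == 1

    def test_mean_aggregation_of_two_variables(self):
        t1 = {(0, "phi"): 0.0, (0, "psi"): 0.0}
        t2 = {(0, "phi"): 20.0, (0, "psi"): 40.0}

        class FakeAlign:
            first_position = 1
            n_columns = 1
            structures = ["a", "b"]
            cells = {"a": [0], "b": [0]}
            positions = range(1, 2)

            def column_of(self, p):
                return p - 1

        sel = PositionSelection(angles={"phi", "psi"})
        d, n = structure_distance(t1, t2, sel, FakeAlign(), "a", "b")
        assert d == pytest.approx(30.0) and n == 2
        d_rms, _ = structure_distance(t1, t2, sel, FakeAlign(), "a", "b",
                                      aggregation="rms")
        assert d_rms == pytest.approx(np.sqrt((400 + 1600) / 2))
        d_max, _ = structure_distance(t1, t2, sel, FakeAlign(), "a", "b",
                                      aggregation="max")
        assert d_max == pytest.approx(40.0)

    def test_no_comparable_variables_is_an_error(self, ensemble2fam):
        structures, align, maps = self._setup(ensemble2fam)
        la, lb = structures[0].label, structures[1].label
        sel = PositionSelection(angles={"chi4"})  # no Lys/Arg chi4 defined pairs
        empty = {}
        with pytest.raises(EnsembleError, match="no comparable"):
            structure_distance(empty, maps[lb], sel, align, la, lb)


class TestCompleteLinkage:
    def test_three_point_forced_merges(self):
        full = np.array([[0.0, 10.0, 100.0],
                         [10.0, 0.0, 100.0],
                         [100.0, 100.0, 0.0]])
        tree = linkage_complete(matrix_from_full(full, ["A", "B", "C"]))
        (a1, b1, h1), (a2, b2, h2) = tree.merges
        assert {a1, b1} == {0, 1} and h1 == pytest.approx(10.0)
        assert h2 == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_scipy_oracle(self, seed):
        dm = random_distance_matrix(seed)
        tree = linkage_complete(dm)
        Z = scipy_linkage(dm.values, method="complete")
        np.testing.assert_allclose([m[2] for m in tree.merges], Z[:, 2],
                                   atol=1e-9)
        # same merged pairs (as leaf sets) at every step
        def partitions(merges, n):
            members = {i: frozenset([i]) for i in range(n)}
            out = []
            for k, (a, b, _) in enumerate(merges):
                members[n + k] = members[a] | members[b]
                out.append(members[n + k])
            return out
        ours = partitions(tree.merges, 8)
        theirs = partitions([(int(r[0]), int(r[1]), r[2]) for r in Z], 8)
        assert ours == theirs

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_merge_heights(self, seed):
        tree = linkage_complete(random_distance_matrix(seed, n=10))
        heights = [m[2] for m in tree.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_all_equal_distances_tie_break_deterministic(self):
        full = np.full((4, 4), 7.0)
        np.fill_diagonal(full, 0.0)
        tree = linkage_complete(matrix_from_full(full))
        assert [m[2] for m in tree.merges] == [7.0, 7.0, 7.0]
        # smallest-leaf-index tie-break: first merge joins leaves 0 and 1
        assert {tree.merges[0][0], tree.merges[0][1]} == {0, 1}
        tree2 = linkage_complete(matrix_from_full(full))
        assert tree.merges == tree2.merges


class TestCutTree:
    def _three_point_tree(self):
        full = np.array([[0.0, 10.0, 100.0],
                         [10.0, 0.0, 100.0],
                         [100.0, 100.0, 0.0]])
        return linkage_complete(matrix_from_full(full, ["A", "B", "C"]))

    def test_radius_above_root_gives_one_cluster(self):
        result = cut_tree(self._three_point_tree(), radius=150.0)
        assert result.n_clusters == 1

    def test_radius_below_all_merges_gives_singletons(self):
        result = cut_tree(self._three_point_tree(), radius=5.0)
        assert result.n_clusters == 3

    def test_radius_60_splits_far_point(self):
        result = cut_tree(self._three_point_tree(), radius=60.0)
        assert result.n_clusters == 2
        assert result.labels["A"] == result.labels["B"] != result.labels["C"]
        # ids ordered by decreasing size
        assert result.labels["A"] == 1 and result.labels["C"] == 2

    def test_merge_at_exact_radius_is_refused(self):
        result = cut_tree(self._three_point_tree(), radius=10.0)
        assert result.n_clusters == 3

    @pytest.mark.parametrize("seed", range(3))
    def test_surviving_clusters_are_radius_apart(self, seed):
        dm = random_distance_matrix(seed)
        full = dm.full()
        radius = float(np.median(full[np.triu_indices(8, 1)]))
        result = cut_tree(linkage_complete(dm), radius=radius)
        groups = {}
        for lab, cid in result.labels.items():
            groups.setdefault(cid, []).append(int(lab[1:]))
        for c1 in groups:
            for c2 in groups:
                if c1 < c2:
                    dmax = max(full[i, j] for i in groups[c1] for j in groups[c2])
                    assert dmax >= radius

    def test_permuting_structures_preserves_partition(self):
        rng = np.random.default_rng(17)
        full = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        full[iu] = rng.uniform(10, 170, len(iu[0]))
        full += full.T
        labels = [f"s{i}" for i in range(6)]
        res1 = cut_tree(linkage_complete(matrix_from_full(full, labels)), 90.0)
        perm = rng.permutation(6)
        res2 = cut_tree(linkage_complete(
            matrix_from_full(full[np.ix_(perm, perm)],
                             [labels[i] for i in perm])), 90.0)
        part1 = {frozenset(l for l, c in res1.labels.items() if c == cid)
                 for cid in set(res1.labels.values())}
        part2 = {frozenset(l for l, c in res2.labels.items() if c == cid)
                 for cid in set(res2.labels.values())}
        assert part1 == part2


class TestOutputs:
    def test_emit_cluster_families_round_trips(self):
        tree = linkage_complete(matrix_from_full(np.array(
            [[0, 5, 90, 90], [5, 0, 90, 90], [90, 90, 0, 5], [90, 90, 5, 0]],
            dtype=float), ["w", "x", "y", "z"]))
        result = cut_tree(tree, radius=60.0)
        entries = parse_structure_list("w A\nx A\ny B\nz B\n")
        # labels for explicit chains carry the :chain suffix
        for e in entries:
            result.labels[e.label] = result.labels.pop(e.basename)
        text = emit_cluster_families(result, entries)
        back = parse_structure_list(text)
        assert [e.basename for e in back] == ["w", "x", "y", "z"]
        assert [e.chain_spec for e in back] == ["A", "A", "B", "B"]
        assert sorted({e.family for e in back}) == ["1", "2"]

    def test_newick_is_parseable_with_correct_leaves(self):
        import dendropy
        dm = random_distance_matrix(2, n=6)
        tree = linkage_complete(dm)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(dm.labels)
        # ultrametric: root-to-leaf path length equals root height for all
        root_h = tree.merges[-1][2]
        for leaf in parsed.leaf_node_iter():
            depth = leaf.distance_from_root()
            assert depth == pytest.approx(root_h, abs=1e-6)


class TestTwoFamilyRecovery:
    def test_families_recovered_at_radius_60(self):
        structures, _ = two_family_ensemble(seed=7, n=10, sd=5.0)
        align = align_by_numbering(structures)
        maps = {s.label: {(r.residue_index, r.angle): r.value
                          for r in all_torsions(s) if r.value is not None}
                for s in structures}
        sel = PositionSelection(ranges=[(9, 13)], angles={"phi", "psi"})
        dm, tree, result = cluster(maps, [s.label for s in structures], sel,
                                   align, radius=60.0)
        assert result.n_clusters == 2
        # 100% purity: cluster id is a function of the family
        by_family = {}
        for s in structures:
            by_family.setdefault(s.family, set()).add(result.labels[s.label])
        assert all(len(v) == 1 for v in by_family.values())
        assert by_family["closed"] != by_family["open"]
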