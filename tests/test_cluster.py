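import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ohp.cluster import average_linkage, signature_distance_matrix
from ohp.core import OhpError
from ohp.signature import BLOCKS, Signature, SignatureEntry


def _signature(label, z_vector):
    entries = []
    i = 0
    for block, _, _ in BLOCKS:
        for p in range(10):
            entries.append(
                SignatureEntry(
                    index=i + 1, block=block, parameter=f"param{p}", z=float(z_vector[i]), n=10
                )
            )
            i += 1
    return Signature(label=label, entries=entries)


class TestSignatureDistanceMatrix:
    def test_identical_signatures_have_zero_distance(self):
        a = _signature("A", np.arange(40.0))
        b = _signature("B", np.arange(40.0))
        d = signature_distance_matrix([a, b])
        np.testing.assert_allclose(d, 0.0)

    def test_closed_form_distance(self):
        z = np.zeros(40)
        z2 = z.copy()
        z2[[0, 5, 12, 33]] += 3.0  # four entries differing by +3
        d = signature_distance_matrix([_signature("A", z), _signature("B", z2)])
        assert d[0, 1] == pytest.approx(np.sqrt(4 * 9))
        assert d[1, 0] == d[0, 1] and d[0, 0] == 0.0

    def test_distal_subset_masks_proximal_differences(self):
        z = np.zeros(40)
        z2 = z.copy()
        z2[10:20] = 7.0  # Mito-Proximal block only
        sigs = [_signature("A", z), _signature("B", z2)]
        assert signature_distance_matrix(sigs, "distal")[0, 1] == 0.0
        assert signature_distance_matrix(sigs, "proximal")[0, 1] > 0.0

    def test_subset_sizes(self):
        sig = _signature("A", np.zeros(40))
        assert len(sig.subset_indices("full")) == 40
        assert len(sig.subset_indices("distal")) == 20
        assert len(sig.subset_indices("proximal")) == 20

    def test_mismatched_ordering_rejected(self):
        a = _signature("A", np.zeros(40))
        b = _signature("B", np.zeros(40))
        b.entries[0] = SignatureEntry(1, b.entries[0].block, "other", 0.0, 10)
        with pytest.raises(OhpError, match="ordering"):
            signature_distance_matrix([a, b])


class TestAverageLinkage:
    def test_hand_computed_three_point_case(self):
        # d(A,B)=1, d(A,C)=d(B,C)=4: merge (A,B) at 1, then with C at 4.
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        dendro = average_linkage(d, ["A", "B", "C"])
        assert len(dendro.merges) == 2
        assert dendro.merges[0][:3] == (0, 1, 1.0)
        assert dendro.merges[1][2] == pytest.approx(4.0)

    def test_all_equal_distances_merge_at_same_height(self):
        n = 5
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        dendro = average_linkage(d)
        np.testing.assert_allclose(dendro.heights, 2.0)

    def test_duplicate_leaf_merges_first_at_zero(self):
        pts = np.array([[0.0], [0.0], [5.0], [9.0]])
        d = np.abs(pts - pts.T)
        dendro = average_linkage(d, ["dup1", "dup2", "far", "farther"])
        assert dendro.merges[0][2] == 0.0
        assert set(dendro.merges[0][:2]) == {0, 1}

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(OhpError):
            average_linkage(np.zeros((1, 1)), ["A"])

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.uniform(0, 10, size=(8, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dendro = average_linkage(d)
            h = dendro.heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_matches_scipy_reference_heights(self):
        """Independent-oracle check: merge heights equal scipy's UPGMA."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(3, 13))
            pts = rng.uniform(0, 10, size=(n, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            ours = average_linkage(d).heights
            ref = linkage(squareform(d, checks=False), method="average")[:, 2]
            np.testing.assert_allclose(np.sort(ours), np.sort(ref), atol=1e-9)

    def test_permutation_changes_labels_not_heights(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, size=(7, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"c{i}" for i in range(7)]
        base = average_linkage(d, labels)
        perm = rng.permutation(7)
        shuffled = average_linkage(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        np.testing.assert_allclose(np.sort(base.heights), np.sort(shuffled.heights), atol=1e-12)

    def test_newick_export_is_a_valid_ultrametric_tree(self):
        import dendropy

        pts = np.array([[0.0], [1.0], [5.0], [5.5]])
        d = np.abs(pts - pts.T)
        dendro = average_linkage(d, ["A", "B", "C", "D"])
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {"A", "B", "C", "D"}
        depths = {
            leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        }
        assert max(depths.values()) - min(depths.values()) < 1e-9  # ultrametric
        assert max(depths.values()) == pytest.approx(dendro.heights[-1] / 2)


class TestEndToEndClusterStructure:
    def test_slowdown_replicates_merge_before_controls(self, slowdown_results):
        from scipy.cluster.hierarchy import fcluster

        _, dendro = slowdown_results
        flat = fcluster(dendro.to_linkage_matrix(), t=2, criterion="maxclust")
        groups = {}
        for label, cl in zip(dendro.leaves, flat):
            groups.setdefault(cl, set()).add(label)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"Ctrl", "CtrlRep"}),
            frozenset({"Slow", "SlowRep"}),
        }
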