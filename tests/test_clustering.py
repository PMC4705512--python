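import numpy as np
import pytest

from delmap.clustering import (
    binary_distance,
    build_clustered_matrix,
    cluster_markers,
    dumps_clustered,
    ward_cluster,
)
from delmap.matrix import DeletionMatrix

from conftest import random_matrix


def matrix_from_columns(cols):
    states = np.array(cols).T
    return DeletionMatrix(
        tuple(f"mu{i}" for i in range(states.shape[0])),
        tuple(chr(ord("A") + j) for j in range(states.shape[1])),
        states,
    )


class TestBinaryDistance:
    def test_hand_evaluated_cases(self):
        # among mutants where at least one marker is present, the fraction
        # where exactly one is: (1,1,0,0) vs (1,0,1,0) -> on-union {1,2,3},
        # discordant {2,3} -> 2/3
        m = matrix_from_columns([[1, 1, 0, 0], [1, 0, 1, 0]])
        d = binary_distance(m)
        assert d[0, 1] == pytest.approx(2 / 3)

    def test_identical_profiles_at_zero_full_discordance_at_one(self):
        m = matrix_from_columns([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        d = binary_distance(m)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_never_present_conventions(self):
        m = matrix_from_columns([[0, 0], [0, 0], [1, 0]])
        d = binary_distance(m)
        assert d[0, 1] == 0.0  # two all-deleted profiles agree
        assert d[0, 2] == 1.0  # all-deleted vs anything else

    def test_symmetric_zero_diagonal_unit_range(self, rng):
        d = binary_distance(random_matrix(rng, 7, 9))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1


class TestWardCluster:
    def test_cut_at_leaves_and_root(self, rng):
        m = random_matrix(rng, 5, 6)
        d = binary_distance(m)
        assert all(c.num == 1 for c in ward_cluster(d, 6))
        (root,) = ward_cluster(d, 1)
        assert root.num == 6

    def test_nearest_pair_merges_first(self):
        m = matrix_from_columns([[1, 1, 1, 1], [1, 1, 1, 0], [0, 0, 1, 1]])
        clusters = cluster_markers(m, 2)
        members = sorted(tuple(sorted(c.members)) for c in clusters)
        assert members == [("A", "B"), ("C",)]

    def test_out_of_range_count_rejected(self, rng):
        d = binary_distance(random_matrix(rng, 4, 5))
        for bad in (0, 6):
            with pytest.raises(ValueError):
                ward_cluster(d, bad)

    def test_invariant_to_marker_order(self, rng):
        m = random_matrix(rng, 8, 10)
        perm = list(rng.permutation(m.n_markers))
        shuffled = m.reorder_markers([m.marker_names[i] for i in perm])
        a = {frozenset(c.members) for c in cluster_markers(m, 4)}
        b = {frozenset(c.members) for c in cluster_markers(shuffled, 4)}
        assert a == b

    def test_matches_r_hclust_ward_d2(self, rng, tmp_path):
        """Cross-check partition against R's dist(binary) + hclust(ward.D2)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        m = random_matrix(rng, 20, 15)
        np.savetxt(tmp_path / "m.csv", m.states, fmt="%d", delimiter=",")
        script = (
            f'x <- as.matrix(read.csv("{tmp_path / "m.csv"}", header=FALSE));'
            'h <- hclust(dist(t(x), method="binary"), method="ward.D2");'
            'cat(cutree(h, k=5), sep=" ")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_labels = [int(v) for v in out.stdout.split()]
        r_parts = {}
        for name, lab in zip(m.marker_names, r_labels):
            r_parts.setdefault(lab, set()).add(name)
        ours = {frozenset(c.members) for c in cluster_markers(m, 5)}
        assert ours == {frozenset(s) for s in r_parts.values()}


class TestClusteredMatrix:
    def test_states_count_present_members(self, rng):
        m = random_matrix(rng, 6, 8)
        clusters = cluster_markers(m, 3)
        cm = build_clustered_matrix(m, clusters, smooth=False)
        for j, c in enumerate(cm.clusters):
            idx = [m.marker_names.index(x) for x in c.members]
            assert np.array_equal(cm.cluster_states[:, j], m.states[:, idx].sum(axis=1))

    @pytest.mark.parametrize(
        "member_states,smoothed_state",
        [
            ((1, 1, 1, 0), 4),  # num=4, one deletion -> PCR error, reset to full
            ((1, 1, 0, 0), 2),  # two deletions: rule does not apply
        ],
    )
    def test_smoothing_rule_num4(self, member_states, smoothed_state):
        m = matrix_from_columns([[s] for s in member_states])
        clusters = cluster_markers(m, 1)
        cm = build_clustered_matrix(m, clusters, smooth=True)
        assert cm.cluster_states[0, 0] == smoothed_state

    def test_smoothing_skips_small_clusters(self):
        m = matrix_from_columns([[1], [1], [0]])  # num=3, state 2 stays
        cm = build_clustered_matrix(m, cluster_markers(m, 1), smooth=True)
        assert cm.cluster_states[0, 0] == 2

    def test_smoothing_idempotent_and_never_decreases(self, rng):
        m = random_matrix(rng, 10, 12)
        clusters = cluster_markers(m, 3)
        raw = build_clustered_matrix(m, clusters, smooth=False)
        once = build_clustered_matrix(m, clusters, smooth=True)
        assert np.all(once.cluster_states >= raw.cluster_states)
        nums = once.nums
        again = once.cluster_states.copy()
        mask = (nums[None, :] > 3) & (again == nums[None, :] - 1)
        assert not mask.any()

    def test_non_partition_rejected(self, rng):
        m = random_matrix(rng, 4, 5)
        clusters = cluster_markers(m, 2)
        with pytest.raises(ValueError, match="partition"):
            build_clustered_matrix(m, clusters[:1])

    def test_emission_layout(self, rng):
        m = random_matrix(rng, 3, 4)
        cm = build_clustered_matrix(m, cluster_markers(m, 2), smooth=False)
        lines = dumps_clustered(cm).splitlines()
        assert len(lines) == 2 + m.n_mutants
        assert lines[1].split(",")[:-1] == [str(c.num) for c in cm.clusters]
        assert lines[2].rsplit(",", 1)[1] == m.mutant_names[0]
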