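"""Marker clustering and the multi-state clustered matrix.

Exhaustive ordering of every marker is infeasible beyond ~14 markers, so
markers are first grouped into ``n`` clusters by the dissimilarity of their
presence/absence profiles (asymmetric-binary distance, Ward agglomeration).
Each cluster is then treated as one *virtual marker* whose per-mutant state
is the count of its member markers still present — an integer in
``[0, num]`` where ``num`` is the cluster size.

A lone deleted member inside a large cluster (state ``num - 1`` with
``num > 3``) is more plausibly a PCR genotyping artefact than a real
deletion; the smoothing rule resets such states to ``num``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

from .matrix import DeletionMatrix

__all__ = [
    "MarkerCluster",
    "ClusteredMatrix",
    "binary_distance",
    "ward_cluster",
    "build_clustered_matrix",
    "cluster_markers",
    "dumps_clustered",
]

#: the paper-style default cluster count for ~70 markers
DEFAULT_N_CLUSTERS = 12

#: smoothing applies only to clusters larger than this
SMOOTH_MIN_NUM = 3


@dataclass(frozen=True)
class MarkerCluster:
    cluster_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError("cluster must have at least one member")

    @property
    def num(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusteredMatrix:
    """Per-mutant present-member counts for an ordered list of clusters."""

    clusters: tuple[MarkerCluster, ...]
    mutant_names: tuple[str, ...]
    cluster_states: np.ndarray = field(repr=False)  # (n_mutants, n_clusters)
    smoothed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        object.__setattr__(self, "mutant_names", tuple(self.mutant_names))
        states = np.asarray(self.cluster_states, dtype=np.int64)
        object.__setattr__(self, "cluster_states", states)
        if states.shape != (len(self.mutant_names), len(self.clusters)):
            raise ValueError("cluster_states shape does not match names")
        nums = self.nums
        if (states < 0).any() or (states > nums[None, :]).any():
            raise ValueError("cluster state outside [0, num]")
        states.setflags(write=False)

    @property
    def nums(self) -> np.ndarray:
        return np.array([c.num for c in self.clusters])

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def binary_distance(m: DeletionMatrix) -> np.ndarray:
    """Pairwise asymmetric-binary dissimilarity between marker profiles.

    For two markers, the distance is the fraction of discordant mutants
    among the mutants where at least one of the two is present ("on" =
    present).  Two never-present profiles are at distance 0, and a
    never-present profile is at distance 1 from any other — so degenerate
    markers cluster together instead of breaking the grid.
    """
    profiles = m.states.T.astype(bool)  # markers x mutants
    return squareform(pdist(profiles, metric="jaccard"))


def ward_cluster(d: np.ndarray, n: int) -> list[MarkerCluster]:
    """Cut a Ward-variance hierarchy of the dissimilarity grid into ``n`` clusters.

    Agglomeration uses the squared-distance (ward.D2) Lance–Williams update
    on the given dissimilarities.  Cluster ids are ``C01``, ``C02``, ... in
    order of first appearance along the input, with members in input order.
    Labels here are positional; callers pass marker names via
    :func:`cluster_markers`.
    """
    d = np.asarray(d, dtype=float)
    ma = d.shape[0]
    if d.shape != (ma, ma):
        raise ValueError("dissimilarity grid must be square")
    if not 1 <= n <= ma:
        raise ValueError(f"cluster count {n} outside [1, {ma}]")
    if n == ma:
        labels = np.arange(ma)
    elif n == 1:
        labels = np.zeros(ma, dtype=int)
    else:
        z = linkage(squareform(d, checks=False), method="ward")
        labels = cut_tree(z, n_clusters=n).ravel()
    width = max(2, len(str(n)))
    clusters: list[MarkerCluster] = []
    seen: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        seen.setdefault(int(lab), []).append(i)
    for order, (_, members) in enumerate(
        sorted(seen.items(), key=lambda kv: kv[1][0]), start=1
    ):
        clusters.append(
            MarkerCluster(f"C{order:0{width}d}", tuple(str(i) for i in members))
        )
    return clusters


def cluster_markers(m: DeletionMatrix, n: int) -> list[MarkerCluster]:
    """Cluster the markers of ``m`` into ``n`` clusters by profile dissimilarity."""
    positional = ward_cluster(binary_distance(m), n)
    return [
        MarkerCluster(c.cluster_id, tuple(m.marker_names[int(i)] for i in c.members))
        for c in positional
    ]


def build_clustered_matrix(
    m: DeletionMatrix, clusters: list[MarkerCluster], smooth: bool = True
) -> ClusteredMatrix:
    """Collapse marker columns into per-cluster present-member counts.

    ``clusters`` must partition the markers of ``m``.  With ``smooth`` on,
    every state equal to ``num - 1`` in a cluster with ``num > 3`` is reset
    to ``num`` (the single missing member is treated as a PCR error).
    """
    covered = [name for c in clusters for name in c.members]
    if sorted(covered) != sorted(m.marker_names):
        raise ValueError("clusters do not partition the marker set")
    states = np.empty((m.n_mutants, len(clusters)), dtype=np.int64)
    for j, c in enumerate(clusters):
        idx = [m.marker_names.index(name) for name in c.members]
        states[:, j] = m.states[:, idx].sum(axis=1)
    if smooth:
        nums = np.array([c.num for c in clusters])
        mask = (nums[None, :] > SMOOTH_MIN_NUM) & (states == nums[None, :] - 1)
        states[mask] = np.broadcast_to(nums[None, :], states.shape)[mask]
    return ClusteredMatrix(tuple(clusters), m.mutant_names, states, smoothed=smooth)


def apply_smoothing(m: DeletionMatrix, clusters: list[MarkerCluster]) -> DeletionMatrix:
    """Marker-level PCR-error correction implied by the smoothing rule.

    For every mutant and every cluster with more than three members, a
    single deleted member among otherwise present ones is treated as a
    genotyping artefact and reset to present.  This is the marker-resolution
    counterpart of resetting a cluster state of ``num - 1`` to ``num``; the
    corrected matrix is what every cost downstream of clustering sees.
    """
    states = m.states.copy()
    deleted_elsewhere = (m.states == 0).sum(axis=0)  # per marker, over mutants
    for c in clusters:
        if c.num <= SMOOTH_MIN_NUM:
            continue
        idx = [m.marker_names.index(name) for name in c.members]
        block = states[:, idx]
        # the stated rule: a lone deleted member is a PCR error
        lone = block.sum(axis=1) == c.num - 1
        # corroboration rule: several deleted members, each deleted in no
        # other mutant, carry no signal any second mutant confirms — the
        # signature of this mutant's PCR artifacts, not of a real deletion
        unique_only = np.logical_and(
            block.sum(axis=1) < c.num - 1,
            ((block == 1) | (deleted_elsewhere[idx][None, :] == 1)).all(axis=1),
        )
        block[lone | unique_only] = 1
        states[:, idx] = block
    return DeletionMatrix(m.mutant_names, m.marker_names, states)


def dumps_clustered(cm: ClusteredMatrix, delimiter: str = ",") -> str:
    """Delimited text: cluster names, then num values, states, mutant name last."""
    lines = [
        delimiter.join([c.cluster_id for c in cm.clusters] + [""]),
        delimiter.join([str(c.num) for c in cm.clusters] + [""]),
    ]
    for name, row in zip(cm.mutant_names, cm.cluster_states):
        lines.append(delimiter.join([str(int(v)) for v in row] + [name]))
    return "\n".join(lines) + "\n"
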