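"""Obligate-break cost model.

An adjacency between a present marker and a deleted marker in one mutant
implies at least one physical chromosome break; the best marker order
minimises the total number of such obligate breaks over all mutants.

Candidate orders are evaluated between two virtual end markers.  The start
end of the mapped region is present in every mutant.  The opposite end is
either deleted in every mutant ("del" option, for regions known to end in
deletable sequence) or copies the status of its neighbour and contributes
nothing ("any" option, tolerant of phenotype-ascertained mutant panels).

Clusters generalise markers to multi-state virtual markers: walking an
order, each mutant carries a present/deleted classification that starts
present at the region end and is updated cluster by cluster — a fully
present cluster (state == num) after a present predecessor costs nothing, a
partly or wholly deleted one costs one break and flips the classification
to deleted; after a deleted predecessor any present member (state > 0)
costs one break and flips back to present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusteredMatrix
from .matrix import DeletionMatrix

__all__ = ["EndOption", "PathCost", "breaks", "pair_cost", "path_cost", "clustered_path_cost"]


END_OPTIONS = ("del", "any")


def _check_option(opt: str) -> str:
    opt = opt.lower()
    if opt not in END_OPTIONS:
        raise ValueError(f"end option must be one of {END_OPTIONS}, got {opt!r}")
    return opt


#: alias used in signatures; the two values are "del" and "any"
EndOption = str


@dataclass(frozen=True)
class PathCost:
    """Total obligate-break count of one order, with its per-mutant split."""

    total: int
    per_mutant: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_mutant", tuple(int(v) for v in self.per_mutant))
        if self.total != sum(self.per_mutant):
            raise ValueError("total does not equal the per-mutant sum")


def breaks(si: int, sj: int) -> int:
    """1 if adjacent binary states differ (one obligate break), else 0."""
    if si not in (0, 1) or sj not in (0, 1):
        raise ValueError("breaks() takes binary states")
    return int(si != sj)


def pair_cost(m: DeletionMatrix, i: str, j: str) -> int:
    """Number of mutants discordant between markers ``i`` and ``j``."""
    return int(np.sum(m.column(i) != m.column(j)))


def path_cost(m: DeletionMatrix, order: list[str] | tuple[str, ...], opt: EndOption) -> PathCost:
    """Total breaks of a complete marker order, virtual ends included."""
    opt = _check_option(opt)
    if sorted(order) != sorted(m.marker_names):
        raise ValueError("order is not a permutation of the matrix markers")
    pos = {name: j for j, name in enumerate(m.marker_names)}
    idx = [pos[name] for name in order]
    s = m.states[:, idx]
    per = (s[:, :-1] != s[:, 1:]).sum(axis=1)
    per = per + (s[:, 0] == 0)  # start end: present in every mutant
    if opt == "del":
        per = per + (s[:, -1] == 1)  # all-deleted end
    return PathCost(int(per.sum()), tuple(int(v) for v in per))


def clustered_path_cost(
    cm: ClusteredMatrix, order: list[str] | tuple[str, ...], opt: EndOption
) -> PathCost:
    """Total breaks of a cluster order under classification propagation."""
    opt = _check_option(opt)
    ids = [c.cluster_id for c in cm.clusters]
    if sorted(order) != sorted(ids):
        raise ValueError("order is not a permutation of the clusters")
    col = {cid: k for k, cid in enumerate(ids)}
    nums = cm.nums
    mu = len(cm.mutant_names)
    classified = np.ones(mu, dtype=bool)  # start virtual marker: present
    per = np.zeros(mu, dtype=np.int64)
    for cid in order:
        k = col[cid]
        s = cm.cluster_states[:, k]
        full = s == nums[k]
        some = s > 0
        per += np.where(classified, ~full, some)
        classified = np.where(classified, full, some)
    if opt == "del":
        per += classified  # break iff still classified present at the deleted end
    return PathCost(int(per.sum()), tuple(int(v) for v in per))
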