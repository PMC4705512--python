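"""Exact minimum-break ordering by branch and bound.

Ordering markers to minimise obligate breaks is a travelling-salesman-path
problem: items (markers or clusters) are cities, adjacency break counts are
edge costs, and the two virtual end markers pin the path's ends.  The
search enumerates *every* order attaining the global minimum — co-optimal
maps measure how ambiguous the data leave the map — by depth-first
branch and bound.  All adjacency costs are non-negative, so the partial
cost plus a per-item lower bound (a partly deleted cluster always costs at
least one break to enter) admissibly prunes the tree.

The full pipeline clusters the markers, orders the clusters exactly, then
recursively orders the actual markers inside each cluster between virtual
markers representing the adjoining clusters, and finally re-ranks every
assembled complete marker order by its exact break count (on the
PCR-corrected matrix when smoothing is on), keeping the minimum only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice, product

import numpy as np

from .clustering import (
    ClusteredMatrix,
    MarkerCluster,
    apply_smoothing,
    build_clustered_matrix,
    cluster_markers,
)
from .cost import EndOption, _check_option
from .matrix import DeletionMatrix

__all__ = [
    "SearchItem",
    "MapSolution",
    "SearchCeilingError",
    "DEFAULT_CEILING",
    "solve_exact",
    "refine_within_cluster",
    "profile_groups",
    "collapse_order",
    "map_pipeline",
]

#: largest number of orderable items one exact search will accept
DEFAULT_CEILING = 14

#: how many breaks above the clustered-walk minimum the pipeline still
#: refines (the walk only approximates the assembled map's break count)
DEFAULT_SLACK = 2

#: enumeration cap for weakly constrained inputs; large enough that every
#: search of <= 8 items (8! = 40320 orders) is still exhaustive
DEFAULT_MAX_ORDERS = 50_000

#: search-tree nodes between band-tightening steps of one exact search;
#: the default keeps any search of <= 8 items (~1e5 nodes even with full
#: ties) exhaustive, while the pipeline uses a tighter budget internally
NODE_BUDGET = 200_000
PIPELINE_NODE_BUDGET = 40_000

#: pipeline caps: cluster orders refined, candidate member orders kept per
#: cluster, and co-optimal maps reported
MAX_CLUSTER_ORDERS = 300
MAX_ORDERS_PER_CLUSTER = 2_000
MAX_BEST_MAPS = 20_000


class SearchCeilingError(ValueError):
    """Raised when an exact search would span too many items."""


@dataclass(frozen=True)
class SearchItem:
    """One orderable unit: a marker (num=1) or a cluster (num = member count)."""

    name: str
    states: np.ndarray = field(repr=False)  # per-mutant present-member count
    num: int = 1

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "states", s)
        if (s < 0).any() or (s > self.num).any():
            raise ValueError(f"item {self.name!r}: state outside [0, {self.num}]")


@dataclass(frozen=True)
class MapSolution:
    """All minimum-break maps of one matrix.

    ``best_orders`` holds one representative complete marker order per
    collapsed map: markers with identical deletion profiles are mutually
    interchangeable at zero cost, so each such profile group is kept as a
    contiguous block and orders differing only inside blocks are counted
    once.  ``n_best_maps`` is the number of distinct collapsed maps.

    When the pipeline ran with PCR-error smoothing, ``best_cost`` and the
    profile groups refer to the smoothing-corrected matrix (isolated
    single-marker deletions inside large clusters reset to present), not
    the raw input.
    """

    best_cost: int
    best_orders: tuple[tuple[str, ...], ...]
    n_best_maps: int
    profile_groups: tuple[tuple[str, ...], ...]
    end_option: EndOption
    n_clusters: int


def _items_from_matrix(m: DeletionMatrix) -> list[SearchItem]:
    return [SearchItem(name, m.states[:, j].astype(np.int64), 1)
            for j, name in enumerate(m.marker_names)]


def _items_from_clustered(cm: ClusteredMatrix) -> list[SearchItem]:
    return [SearchItem(c.cluster_id, cm.cluster_states[:, j], c.num)
            for j, c in enumerate(cm.clusters)]


def _enumerate_optimal(
    items: list[SearchItem],
    init_class: np.ndarray,
    terminal,
    ceiling: int = DEFAULT_CEILING,
    slack: int = 0,
    max_orders: int = DEFAULT_MAX_ORDERS,
    node_budget: int = NODE_BUDGET,
) -> tuple[int, list[tuple[str, ...]]]:
    """All orders of ``items`` within ``slack`` of the minimal break count.

    ``init_class`` is the per-mutant present/deleted classification entering
    the first item; ``terminal(classification) -> int`` prices the final
    adjacency (the right virtual marker).  The returned order list is
    deterministic, sorted by (break count, lexicographic item name).

    ``max_orders`` bounds the enumeration on degenerate, weakly constrained
    inputs: when more orders than that fall inside the slack band, the band
    is tightened one break at a time, and if the exact ties alone exceed the
    cap the surplus is cut off (the minimum itself is always exact).
    """
    n = len(items)
    if n > ceiling:
        raise SearchCeilingError(
            f"{n} items exceed the exact-search ceiling of {ceiling}; "
            "increase the number of clusters (or the ceiling)"
        )
    order_idx = sorted(range(n), key=lambda i: items[i].name)
    names = [items[i].name for i in order_idx]
    s = np.stack([items[i].states for i in order_idx])  # (n, mu)
    nums = np.array([items[i].num for i in order_idx])[:, None]
    mu = s.shape[1]
    full_mask = (1 << mu) - 1

    def to_mask(bools: np.ndarray) -> int:
        mask = 0
        for m_idx in np.flatnonzero(bools):
            mask |= 1 << int(m_idx)
        return mask

    # per-item bitmasks over mutants: break and classification outcomes for
    # a present / deleted predecessor (the DFS hot loop runs on ints)
    bp = [to_mask(s[i] < nums[i]) for i in range(n)]
    bd = [to_mask(s[i] > 0) for i in range(n)]
    cp = [to_mask(s[i] == nums[i]) for i in range(n)]
    cd = bd  # some member present -> classified present after a deleted pred

    # Admissible pairwise bound: edge_lb[i][j] sums, over mutants, the
    # cheapest break into j given any classification i can hand over (the
    # classification is pinned unless i is partly deleted).  Every item in a
    # suffix must be entered from some other suffix item (or the branch
    # item), so column minima of edge_lb lower-bound the suffix cost.
    big = 1 << 40
    edge_lb = [[big] * n for _ in range(n)]
    for i in range(n):
        definite = full_mask & ~(cp[i] ^ cd[i])  # mutants where i's class is pinned
        for j in range(n):
            if i == j:
                continue
            pinned_cost = (cp[i] & bp[j]) | (full_mask & ~cp[i] & bd[j])
            floor_cost = bp[j] & bd[j]
            edge_lb[i][j] = (
                (definite & pinned_cost) | (full_mask & ~definite & floor_cost)
            ).bit_count()

    best = np.inf
    eff_slack = slack
    tie_margin = 0  # becomes -1 once the cap is hit at zero slack
    kept: list[tuple[int, tuple[int, ...]]] = []
    path: list[int] = []
    # weakly constrained inputs can hide astronomically many near-tied
    # orders; a node budget progressively narrows the accepted band (and
    # finally freezes tie collection) so one search stays bounded.  The
    # schedule depends only on the deterministic traversal order.
    nodes = 0
    next_check = node_budget
    hard_limit = 4 * node_budget
    aborted = False

    def compact() -> None:
        # tighten the accepted band until the kept list fits the cap
        nonlocal eff_slack, tie_margin
        kept[:] = [e for e in kept if e[0] <= best + eff_slack]
        while len(kept) > max_orders and eff_slack > 0:
            eff_slack -= 1
            kept[:] = [e for e in kept if e[0] <= best + eff_slack]
        if len(kept) > max_orders:
            kept.sort()
            del kept[max_orders:]
            tie_margin = -1  # stop collecting ties; improvements only

    def dfs(classified: int, cost: int, unvisited: list[int]) -> None:
        nonlocal best, tie_margin, eff_slack, nodes, next_check, aborted
        if aborted:
            return
        nodes += 1
        if nodes >= next_check:
            next_check += node_budget
            if eff_slack > 0:
                eff_slack -= 1
                kept[:] = [e for e in kept if e[0] <= best + eff_slack]
            elif nodes >= hard_limit:
                aborted = True
                return
            else:
                tie_margin = -1
        inv = full_mask & ~classified
        if not unvisited:
            total = cost + terminal(classified, inv)
            if total < best:
                best = total
                tie_margin = 0
                compact()
            if total <= best + eff_slack + tie_margin:
                kept.append((total, tuple(path)))
                if len(kept) > max_orders:
                    compact()
            return
        # min in-edge per unvisited item over the other unvisited items;
        # after branching on i, every j != i is entered from some item in
        # unvisited \ {j}, so the suffix bound for child i is their sum
        # without i's own term
        suffix = 0
        col_min = {}
        if len(unvisited) > 1:
            for j in unvisited:
                cm_j = big
                for i in unvisited:
                    if i != j and edge_lb[i][j] < cm_j:
                        cm_j = edge_lb[i][j]
                col_min[j] = cm_j
                suffix += cm_j
        else:
            col_min[unvisited[0]] = 0
        children = sorted(
            (((classified & bp[i]) | (inv & bd[i])).bit_count(), i) for i in unvisited
        )
        for inc, i in children:
            if aborted:
                return
            if cost + inc + suffix - col_min[i] > best + eff_slack + tie_margin:
                continue
            path.append(i)
            rest = [j for j in unvisited if j != i]
            dfs((classified & cp[i]) | (inv & cd[i]), cost + inc, rest)
            path.pop()

    dfs(to_mask(np.asarray(init_class, dtype=bool)), 0, list(range(n)))
    final = sorted(e for e in kept if e[0] <= best + eff_slack)
    return int(best), [tuple(names[i] for i in o) for _, o in final]


def _terminal_for(opt: EndOption):
    if opt == "del":
        # all-deleted end: one break per mutant still classified present
        return lambda c, inv: c.bit_count()
    return lambda c, inv: 0  # "any" end copies its neighbour


def _terminal_item(item: SearchItem):
    bp = 0
    bd = 0
    for m_idx, (state, partial) in enumerate(
        zip(item.states, item.states < item.num)
    ):
        if partial:
            bp |= 1 << m_idx
        if state > 0:
            bd |= 1 << m_idx

    def terminal(c: int, inv: int) -> int:
        return ((c & bp) | (inv & bd)).bit_count()

    return terminal


def solve_exact(
    source: DeletionMatrix | ClusteredMatrix | list[SearchItem],
    opt: EndOption,
    flank: tuple[np.ndarray, SearchItem | None] | None = None,
    ceiling: int = DEFAULT_CEILING,
    slack: int = 0,
    node_budget: int = NODE_BUDGET,
) -> tuple[int, list[tuple[str, ...]]]:
    """Globally minimal break count and *all* orders attaining it.

    ``source`` may be a plain matrix (markers are the items), a clustered
    matrix (clusters are the items), or a prepared item list.  ``flank``
    replaces the default virtual ends for within-cluster refinement: a
    per-mutant classification entering from the left, and the adjoining
    right item (``None`` keeps the end-of-region virtual marker).
    """
    opt = _check_option(opt)
    if isinstance(source, DeletionMatrix):
        items = _items_from_matrix(source)
        mu = source.n_mutants
    elif isinstance(source, ClusteredMatrix):
        items = _items_from_clustered(source)
        mu = len(source.mutant_names)
    else:
        items = list(source)
        mu = len(items[0].states)
    if flank is None:
        init = np.ones(mu, dtype=bool)
        terminal = _terminal_for(opt)
    else:
        left, right = flank
        init = np.asarray(left, dtype=bool)
        terminal = _terminal_for(opt) if right is None else _terminal_item(right)
    return _enumerate_optimal(items, init, terminal, ceiling, slack, node_budget=node_budget)


def refine_within_cluster(
    m: DeletionMatrix,
    cluster: MarkerCluster,
    left_class: np.ndarray,
    right: SearchItem | None,
    opt: EndOption,
    ceiling: int = DEFAULT_CEILING,
) -> tuple[int, list[tuple[str, ...]]]:
    """Exactly order one cluster's actual markers between its neighbours.

    ``left_class`` is the per-mutant classification the cluster-order walk
    assigns to the adjoining left cluster (all-present for the first
    cluster); ``right`` is the adjoining right cluster as a virtual marker,
    or ``None`` for the end of the mapped region (handled per ``opt``).
    """
    items = [SearchItem(name, m.column(name).astype(np.int64), 1) for name in cluster.members]
    return solve_exact(items, opt, flank=(left_class, right), ceiling=ceiling)


def profile_groups(m: DeletionMatrix) -> tuple[tuple[str, ...], ...]:
    """Partition markers into groups with identical deletion profiles.

    Markers in one group are pairwise zero-cost adjacent in every mutant, so
    no data can order them; groups are reported in input-column order.
    """
    by_profile: dict[bytes, list[str]] = {}
    for j, name in enumerate(m.marker_names):
        by_profile.setdefault(m.states[:, j].tobytes(), []).append(name)
    return tuple(tuple(g) for g in by_profile.values())


def collapse_order(order: tuple[str, ...], groups: tuple[tuple[str, ...], ...]) -> tuple[str, ...]:
    """Replace markers by their profile-group label, merging consecutive repeats."""
    label = {name: g[0] for g in groups for name in g}
    out: list[str] = []
    for name in order:
        lab = label[name]
        if not out or out[-1] != lab:
            out.append(lab)
    return tuple(out)


def _cluster_walk(
    cm: ClusteredMatrix, order: tuple[str, ...], init: np.ndarray | None = None
) -> list[np.ndarray]:
    """Per-mutant classification after each cluster along ``order``.

    Entry ``k`` is the classification entering cluster ``k`` (entry 0 is
    ``init``, defaulting to the all-present start virtual marker).
    """
    col = {c.cluster_id: j for j, c in enumerate(cm.clusters)}
    nums = cm.nums
    mu = len(cm.mutant_names)
    classified = np.ones(mu, dtype=bool) if init is None else np.asarray(init, bool)
    walk = [classified]
    for cid in order:
        j = col[cid]
        s = cm.cluster_states[:, j]
        classified = np.where(classified, s == nums[j], s > 0)
        walk.append(classified)
    return walk


def map_pipeline(
    m: DeletionMatrix,
    n: int | None = None,
    opt: EndOption = "any",
    smooth: bool = True,
    ceiling: int = DEFAULT_CEILING,
    slack: int = DEFAULT_SLACK,
) -> MapSolution:
    """Cluster, order clusters exactly, refine within clusters, assemble.

    ``n`` defaults to ``min(12, Ma)``.  Markers with identical profiles are
    collapsed to single units before refinement (they are interchangeable at
    zero cost), and every assembled complete marker order is independently
    re-scored with the plain path cost; only the overall minimum is kept.

    The clustered walk only approximates the break count of the assembled
    marker map (smoothing rewrites states, and a cluster's internal
    arrangement can absorb or expose boundary breaks), so restricting
    refinement to exactly cost-minimal cluster and member orders can miss
    maps that are minimal in actual breaks.  ``slack`` widens both search
    levels to orders within that many breaks of their level's minimum; the
    final re-scoring keeps actual-minimum maps only.
    """
    opt = _check_option(opt)
    if n is None:
        n = min(12, m.n_markers)
    if not 1 <= n <= m.n_markers:
        raise ValueError(f"cluster count {n} outside [1, {m.n_markers}]")
    clusters = cluster_markers(m, n)
    cm = build_clustered_matrix(m, clusters, smooth=smooth)
    # with smoothing on, every cost below the cluster level is computed on
    # the PCR-corrected matrix — otherwise the final ranking would reward
    # maps that rearrange markers to absorb isolated genotyping errors,
    # exactly what the correction is there to prevent
    ms = apply_smoothing(m, clusters) if smooth else m
    groups = profile_groups(ms)
    items = {it.name: it for it in _items_from_clustered(cm)}
    by_id = {c.cluster_id: c for c in clusters}
    _, cluster_orders = solve_exact(cm, opt, ceiling=ceiling, slack=slack,
                                    node_budget=PIPELINE_NODE_BUDGET)
    # weakly constrained matrices can leave thousands of near-tied cluster
    # orders; refine the lowest-cost ones only (the list is cost-sorted)
    cluster_orders = cluster_orders[:MAX_CLUSTER_ORDERS]

    cols = {name: ms.column(name) for name in ms.marker_names}
    pair_memo: dict[tuple[str, str], int] = {}

    def pair(a: str, b: str) -> int:
        key = (a, b)
        if key not in pair_memo:
            pair_memo[key] = int(np.count_nonzero(cols[a] != cols[b]))
        return pair_memo[key]

    refine_cache: dict[tuple, list] = {}

    def candidates(cid: str, left_class: np.ndarray, right_id: str | None):
        """Member orders for one cluster in one flank context, as DP blocks.

        The flanked search proposes member orders; each is re-scored with
        plain pairwise breaks and grouped into classes by (first marker,
        last marker, internal cost) — the dynamic programme over blocks
        only ever needs those three, so class members expand lazily during
        backtracking.  Returns a list of
        (first, last, internal, [expanded orders]).
        """
        key = (cid, left_class.tobytes(), right_id)
        if key not in refine_cache:
            units = _group_units(ms, by_id[cid].members)
            unit_map = {u[0]: u for u in units}
            if len(units) == 1:
                orders = [(units[0][0],)]
            else:
                unit_items = [
                    SearchItem(u[0], cols[u[0]].astype(np.int64), 1) for u in units
                ]
                right = items[right_id] if right_id is not None else None
                orders = _order_unit_items(
                    unit_items, left_class, right, opt, ceiling, smooth,
                    PIPELINE_NODE_BUDGET,
                )
            classes: dict[tuple[str, str, int], list[tuple[str, ...]]] = {}
            for uo in orders:
                expanded = tuple(name for u in uo for name in unit_map[u])
                internal = sum(pair(a, b) for a, b in zip(expanded, expanded[1:]))
                classes.setdefault((expanded[0], expanded[-1], internal), []).append(
                    expanded
                )
            refine_cache[key] = [
                (first, last, internal, members)
                for (first, last, internal), members in sorted(classes.items())
            ]
        return refine_cache[key]

    best_cost: int | None = None
    seen: dict[tuple[str, ...], tuple[str, ...]] = {}
    for corder in cluster_orders:
        walk = _cluster_walk(cm, corder)
        blocks = [
            candidates(
                cid,
                walk[pos],
                corder[pos + 1] if pos + 1 < len(corder) else None,
            )
            for pos, cid in enumerate(corder)
        ]
        # exact DP over blocks: the assembled map's break count is the
        # start-end term, each block's internal cost, and the pairwise
        # boundary cost between adjacent blocks' edge markers
        val: list[list[int]] = [
            [
                int(np.count_nonzero(cols[first] == 0)) + internal
                for first, _, internal, _ in blocks[0]
            ]
        ]
        for b in range(1, len(blocks)):
            prev_block = blocks[b - 1]
            prev_val = val[b - 1]
            row = []
            for first, _, internal, _ in blocks[b]:
                row.append(
                    min(
                        prev_val[k] + pair(prev_block[k][1], first)
                        for k in range(len(prev_block))
                    )
                    + internal
                )
            val.append(row)
        ends = []
        for k, (_, last, _, _) in enumerate(blocks[-1]):
            end = int(np.count_nonzero(cols[last] == 1)) if opt == "del" else 0
            ends.append(val[-1][k] + end)
        order_best = min(ends)
        if best_cost is not None and order_best > best_cost:
            continue
        if best_cost is None or order_best < best_cost:
            best_cost = order_best
            seen.clear()
        # backtrack every optimal class chain; expand each chain's member
        # orders lazily, bounded for degenerate weakly constrained inputs
        budget = MAX_BEST_MAPS - len(seen)
        stack = [
            ((), len(blocks) - 1, k)
            for k in reversed(range(len(blocks[-1])))
            if ends[k] == order_best
        ]
        while stack and budget > 0:
            chain, b, k = stack.pop()
            new_chain = (k,) + chain
            if b == 0:
                member_lists = [
                    blocks[pos][idx][3] for pos, idx in enumerate(new_chain)
                ]
                for combo in islice(product(*member_lists), budget):
                    order = tuple(name for part in combo for name in part)
                    key2 = collapse_order(order, groups)
                    if key2 not in seen:
                        seen[key2] = order
                        budget -= 1
                        if budget == 0:
                            break
                continue
            first = blocks[b][k][0]
            need = val[b][k] - blocks[b][k][2]
            for j in reversed(range(len(blocks[b - 1]))):
                if val[b - 1][j] + pair(blocks[b - 1][j][1], first) == need:
                    stack.append((new_chain, b - 1, j))
    assert best_cost is not None
    best_orders = tuple(
        sorted(seen.values(), key=lambda o: collapse_order(o, groups))
    )
    return MapSolution(
        best_cost=best_cost,
        best_orders=best_orders,
        n_best_maps=len(best_orders),
        profile_groups=groups,
        end_option=opt,
        n_clusters=n,
    )


def _order_unit_items(
    unit_items: list[SearchItem],
    left_class: np.ndarray,
    right: SearchItem | None,
    opt: EndOption,
    ceiling: int,
    smooth: bool,
    node_budget: int,
) -> list[tuple[str, ...]]:
    """Minimum-break orders of binary units between two flank contexts.

    Small sets are solved exactly; a set larger than the search ceiling is
    handled the way the whole map is — cluster the units, order the
    clusters between the given flanks, recurse inside each cluster — so
    refinement stays total even for degenerate, weakly structured clusters.
    """
    if len(unit_items) <= ceiling:
        _, orders = _enumerate_optimal(
            unit_items,
            left_class,
            _terminal_for(opt) if right is None else _terminal_item(right),
            ceiling,
            max_orders=MAX_ORDERS_PER_CLUSTER,
            node_budget=node_budget,
        )
        return orders
    profiles = np.stack([(it.states > 0).astype(np.int8) for it in unit_items], axis=1)
    tmp = DeletionMatrix(
        tuple(f"m{i}" for i in range(profiles.shape[0])),
        tuple(it.name for it in unit_items),
        profiles,
    )
    sub_clusters = cluster_markers(tmp, min(12, ceiling))
    cm_sub = build_clustered_matrix(tmp, sub_clusters, smooth=smooth)
    sub_items = {it.name: it for it in _items_from_clustered(cm_sub)}
    by_sub = {c.cluster_id: set(c.members) for c in sub_clusters}
    _, sub_orders = solve_exact(
        cm_sub, opt, flank=(left_class, right), ceiling=ceiling, node_budget=node_budget
    )
    out: list[tuple[str, ...]] = []
    for so in sub_orders[:8]:
        walk = _cluster_walk(cm_sub, so, init=left_class)
        parts: list[list[tuple[str, ...]]] = []
        for pos, scid in enumerate(so):
            members = [it for it in unit_items if it.name in by_sub[scid]]
            r = sub_items[so[pos + 1]] if pos + 1 < len(so) else right
            parts.append(
                _order_unit_items(members, walk[pos], r, opt, ceiling, smooth, node_budget)
            )
        for combo in islice(product(*parts), MAX_ORDERS_PER_CLUSTER - len(out)):
            out.append(tuple(n for part in combo for n in part))
        if len(out) >= MAX_ORDERS_PER_CLUSTER:
            break
    return out


def _group_units(m: DeletionMatrix, members: tuple[str, ...]) -> list[tuple[str, ...]]:
    """Group a cluster's members by identical profile, preserving member order."""
    by_profile: dict[bytes, list[str]] = {}
    for name in members:
        by_profile.setdefault(m.column(name).tobytes(), []).append(name)
    return [tuple(g) for g in by_profile.values()]
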