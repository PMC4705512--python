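"""Simulation study of mapping accuracy.

A scenario fixes generator parameters and mapping settings, runs many
replicates (synthesise a panel with a known true order, shuffle the marker
columns so the solver cannot inherit the truth, map, compare), and reports
two summaries: the percentage of replicates whose true order is among the
co-optimal maps, and the mean number of best-score maps (map ambiguity).

The standard sweep suite varies, one at a time: the genome-wide number of
deleted elements (crossed with biased/non-biased panels and both end
options), the number of mutants, the number of markers (both at a fixed
deleted-element proportion), and the number of injected PCR errors.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .cost import EndOption, _check_option
from .simulate import SimulationSpec, generate, shuffle_markers
from .solver import MapSolution, collapse_order, map_pipeline

__all__ = [
    "Scenario",
    "ScenarioResult",
    "ReplicateRecord",
    "DELETED_PROPORTION",
    "proportional_deletions",
    "is_success",
    "run_scenario",
    "fig2_suite",
]

#: deleted-element proportion used by the mutant- and marker-count sweeps;
#: reproduces 400 deleted elements in a 71-marker x 41-mutant matrix
DELETED_PROPORTION = 0.1374


def proportional_deletions(n_markers: int, n_mutants: int,
                           proportion: float = DELETED_PROPORTION) -> int:
    """Round-half-away-from-zero of proportion * markers * mutants."""
    return int(math.floor(proportion * n_markers * n_mutants + 0.5))


@dataclass(frozen=True)
class Scenario:
    """One sweep point: generator template plus mapping settings."""

    template: SimulationSpec
    end_option: EndOption = "any"
    n_clusters: int = 12
    n_replicates: int = 30
    base_seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        _check_option(self.end_option)
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        # fail before any sampling if a replicate spec would be infeasible
        replace(self.template, seed=None)

    def replicate_seed(self, rep: int) -> tuple[int, int]:
        """Deterministic per-replicate seed stream: (base_seed, replicate)."""
        return (self.base_seed, rep)


@dataclass(frozen=True)
class ReplicateRecord:
    seed: tuple[int, ...]
    success: bool
    best_cost: int
    n_best_maps: int


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    per_replicate: tuple[ReplicateRecord, ...] = field(repr=False)

    @property
    def accuracy_pct(self) -> float:
        n = len(self.per_replicate)
        return 100.0 * sum(r.success for r in self.per_replicate) / n

    @property
    def mean_n_best_maps(self) -> float:
        n = len(self.per_replicate)
        return sum(r.n_best_maps for r in self.per_replicate) / n


def is_success(sol: MapSolution, true_order: tuple[str, ...]) -> bool:
    """Is the true order among the co-optimal maps, up to profile groups?

    Markers with identical deletion profiles cannot be ordered by any data,
    so the comparison collapses each profile group to one unit on both
    sides, and a map read right-to-left is the same physical map, so the
    reversed true order counts as a reconstruction too.
    """
    covered = {name for g in sol.profile_groups for name in g}
    if covered != set(true_order):
        raise ValueError("solution and true order cover different marker sets")
    truth = collapse_order(tuple(true_order), sol.profile_groups)
    for order in sol.best_orders:
        key = collapse_order(order, sol.profile_groups)
        if key == truth or key == truth[::-1]:
            return True
    return False


def run_scenario(sc: Scenario) -> ScenarioResult:
    """Generate, shuffle, map and score every replicate of one scenario."""
    records = []
    for rep in range(sc.n_replicates):
        seed = sc.replicate_seed(rep)
        spec = replace(sc.template, seed=seed)
        matrix, true_order = generate(spec)
        shuffled = shuffle_markers(matrix, np.random.default_rng((*seed, 1)))
        sol = map_pipeline(
            shuffled, n=min(sc.n_clusters, shuffled.n_markers), opt=sc.end_option
        )
        records.append(
            ReplicateRecord(seed, is_success(sol, true_order), sol.best_cost, sol.n_best_maps)
        )
    return ScenarioResult(sc, tuple(records))


def _write_panel(path: str, rows: list[dict]) -> None:
    cols = list(rows[0].keys())
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _scale_sweep(reference: tuple[int, ...], ratio: float, floor: int) -> tuple[int, ...]:
    out = []
    for v in reference:
        w = max(floor, int(math.floor(v * ratio + 0.5)))
        if w not in out:
            out.append(w)
    return tuple(out)


def fig2_suite(
    base_seed: int,
    out_dir: str | os.PathLike | None = None,
    n_replicates: int = 30,
    n_markers: int = 71,
    n_mutants: int = 41,
    deleted_sweep: tuple[int, ...] | None = None,
    mutant_sweep: tuple[int, ...] | None = None,
    marker_sweep: tuple[int, ...] | None = None,
    pcr_sweep: tuple[int, ...] | None = None,
    n_clusters: int = 12,
) -> dict[str, list[ScenarioResult]]:
    """Run the four accuracy sweeps; optionally write one table per panel.

    Panel 1 crosses the deleted-element sweep with biased/non-biased panels
    and both end options; panels 2-4 use the "any" option.  All scenarios
    share the replicate seed stream (common random numbers), so paired
    comparisons between options are not washed out by sampling noise.

    Sweep defaults are the study's values at 71 markers x 41 mutants
    (deleted elements 200/300/400/442/500, mutants 20-60, markers 30-110,
    PCR errors 10/30/50) and scale proportionally at other matrix sizes.
    At the default size and 30 replicates this is ~1000 replicate mappings
    (of order an hour on one core).
    """
    cells = n_markers * n_mutants
    if deleted_sweep is None:
        deleted_sweep = _scale_sweep(
            (200, 300, 400, 442, 500), cells / 2911, 2 * n_mutants
        )
    if mutant_sweep is None:
        mutant_sweep = _scale_sweep((20, 30, 41, 50, 60), n_mutants / 41, 1)
    if marker_sweep is None:
        marker_sweep = _scale_sweep((30, 50, 71, 90, 110), n_markers / 71, 15)
    if pcr_sweep is None:
        pcr_sweep = _scale_sweep((10, 30, 50), cells / 2911, 1)
    results: dict[str, list[ScenarioResult]] = {}

    def scen(template: SimulationSpec, opt: EndOption, label: str) -> ScenarioResult:
        return run_scenario(
            Scenario(template, end_option=opt, n_clusters=n_clusters,
                     n_replicates=n_replicates, base_seed=base_seed, label=label)
        )

    panel = []
    for biased in (False, True):
        for opt in ("any", "del"):
            for d in deleted_sweep:
                t = SimulationSpec(n_markers, n_mutants, d, biased=biased)
                panel.append(scen(t, opt, f"deleted={d} biased={biased} end={opt}"))
    results["deleted_elements"] = panel

    results["mutants"] = [
        scen(
            SimulationSpec(
                n_markers, mu, max(2 * mu, proportional_deletions(n_markers, mu))
            ),
            "any",
            f"mutants={mu}",
        )
        for mu in mutant_sweep
    ]
    results["markers"] = [
        scen(
            SimulationSpec(
                ma, n_mutants, max(2 * n_mutants, proportional_deletions(ma, n_mutants))
            ),
            "any",
            f"markers={ma}",
        )
        for ma in marker_sweep
    ]
    base_deleted = max(2 * n_mutants, proportional_deletions(n_markers, n_mutants))
    results["pcr_errors"] = [
        scen(
            SimulationSpec(n_markers, n_mutants, base_deleted, n_pcr_errors=k),
            "any",
            f"pcr_errors={k}",
        )
        for k in (0,) + tuple(pcr_sweep)
    ]

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, panel_results in results.items():
            rows = [
                {
                    "scenario": r.scenario.label,
                    "accuracy_pct": f"{r.accuracy_pct:.1f}",
                    "mean_n_best_maps": f"{r.mean_n_best_maps:.2f}",
                    "n_replicates": len(r.per_replicate),
                }
                for r in panel_results
            ]
            _write_panel(os.path.join(out_dir, f"{name}.tsv"), rows)
    return results
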