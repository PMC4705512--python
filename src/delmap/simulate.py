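"""Synthetic deletion panels with a known true marker order.

Each simulated mutant carries one contiguous deletion along the true marker
order: an initial adjacent marker pair (placed uniformly, or — for panels
ascertained by phenotype — with a Normal position model centred on the map
middle, sd = half the marker count, resampled until in range) that is then
extended left or right in random increments until the matrix holds exactly
the requested genome-wide number of deleted cells.  Optionally, isolated
single-cell "PCR error" deletions are injected afterwards; these never
touch an existing deletion run, so original run lengths are preserved.

The matrix is emitted with columns in the true order; shuffle the columns
before mapping if the solver must not inherit the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import DeletionMatrix

__all__ = ["SimulationSpec", "generate", "inject_pcr_errors", "shuffle_markers"]


@dataclass(frozen=True)
class SimulationSpec:
    """Generator parameters for one synthetic deletion panel."""

    n_markers: int
    n_mutants: int
    n_deleted: int
    biased: bool = False
    n_pcr_errors: int = 0
    seed: int | tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValueError("need at least two markers")
        if self.n_mutants < 1:
            raise ValueError("need at least one mutant")
        if self.n_deleted < 2 * self.n_mutants:
            raise ValueError(
                f"n_deleted={self.n_deleted} cannot seed every mutant with an "
                f"adjacent pair (need >= {2 * self.n_mutants})"
            )
        if self.n_pcr_errors < 0:
            raise ValueError("n_pcr_errors must be >= 0")
        if self.n_deleted + self.n_pcr_errors > self.n_markers * self.n_mutants:
            raise ValueError("deletion budget exceeds the matrix size")


def _marker_names(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"M{i:0{width}d}" for i in range(1, n + 1))


def _mutant_names(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"mut{i:0{width}d}" for i in range(1, n + 1))


def _initial_pair_start(rng: np.random.Generator, n_markers: int, biased: bool) -> int:
    """0-based start of the initial deleted adjacent pair (start, start+1)."""
    if not biased:
        return int(rng.integers(0, n_markers - 1))
    # centre-biased panels: 1-based pair start ~ round(N(Ma/2, Ma/2)),
    # resampled (not clipped) until it lands inside the map
    while True:
        p = int(np.rint(rng.normal(n_markers / 2.0, n_markers / 2.0)))
        if 1 <= p <= n_markers - 1:
            return p - 1


def generate(spec: SimulationSpec) -> tuple[DeletionMatrix, tuple[str, ...]]:
    """Simulate a deletion panel; returns (matrix, true marker order).

    The matrix holds exactly ``spec.n_deleted`` zero cells before error
    injection (``n_deleted + n_pcr_errors`` after), and each mutant's
    deleted cells form one contiguous run of the true order pre-injection.
    """
    rng = np.random.default_rng(spec.seed)
    ma, mu = spec.n_markers, spec.n_mutants
    # per-mutant deletion run as an inclusive 0-based [lo, hi] interval
    lo = np.empty(mu, dtype=np.int64)
    hi = np.empty(mu, dtype=np.int64)
    for m in range(mu):
        start = _initial_pair_start(rng, ma, spec.biased)
        lo[m], hi[m] = start, start + 1
    n_zero = 2 * mu
    # extend runs until the genome-wide budget is met exactly: each
    # operation deletes a uniformly drawn number of the elements currently
    # neighbouring the deleted runs (a uniform subset of the run ends, so
    # every run grows by at most one element per side and operation); an
    # operation that would overshoot the budget is discarded and redrawn
    while n_zero < spec.n_deleted:
        ends = [(m, side) for m in range(mu)
                for side, room in ((0, int(lo[m])), (1, ma - 1 - int(hi[m])))
                if room > 0]
        k = int(rng.integers(1, len(ends) + 1))
        if n_zero + k > spec.n_deleted:
            continue
        picked = rng.choice(len(ends), size=k, replace=False)
        for p in picked:
            m, side = ends[int(p)]
            if side == 0:
                lo[m] -= 1
            else:
                hi[m] += 1
        n_zero += k
    states = np.ones((mu, ma), dtype=np.int8)
    for m in range(mu):
        states[m, lo[m] : hi[m] + 1] = 0
    matrix = DeletionMatrix(_mutant_names(mu), _marker_names(ma), states)
    true_order = matrix.marker_names
    if spec.n_pcr_errors:
        matrix = inject_pcr_errors(matrix, true_order, spec.n_pcr_errors, rng)
    return matrix, true_order


def inject_pcr_errors(
    m: DeletionMatrix,
    true_order: tuple[str, ...],
    k: int,
    seed: int | np.random.Generator | None = None,
) -> DeletionMatrix:
    """Delete ``k`` isolated single cells without lengthening any deletion run.

    Cells are drawn sequentially, uniformly among present cells whose
    true-order neighbours within the same mutant are all present (chromosome
    ends count as present), so every injected error is a singleton run.
    """
    if k == 0:
        return m
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    col = [m.marker_names.index(name) for name in true_order]
    states = m.states[:, col].copy()  # work in true-order coordinates
    mu, ma = states.shape
    for _ in range(k):
        present = states == 1
        left_ok = np.ones_like(present)
        left_ok[:, 1:] = present[:, :-1]
        right_ok = np.ones_like(present)
        right_ok[:, :-1] = present[:, 1:]
        eligible = np.argwhere(present & left_ok & right_ok)
        if len(eligible) == 0:
            raise ValueError("no eligible cells left for PCR-error injection")
        r, c = eligible[int(rng.integers(0, len(eligible)))]
        states[r, c] = 0
    inv = np.argsort(col)
    return DeletionMatrix(m.mutant_names, m.marker_names, states[:, inv])


def shuffle_markers(
    m: DeletionMatrix, seed: int | np.random.Generator | None = None
) -> DeletionMatrix:
    """Return ``m`` with its marker columns in random order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(m.n_markers)
    return m.reorder_markers([m.marker_names[i] for i in perm])
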