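"""Shared fixtures and independent oracles for the test suite.

The brute-force functions below deliberately re-derive break counts from
first principles (explicit per-mutant state walks over every permutation)
so that solver results can be checked against an implementation that
shares no code with the package's cost model or search.
"""

from itertools import permutations

import numpy as np
import pytest

from delmap.matrix import DeletionMatrix


def random_matrix(rng: np.random.Generator, n_mutants: int, n_markers: int) -> DeletionMatrix:
    states = rng.integers(0, 2, size=(n_mutants, n_markers))
    return DeletionMatrix(
        tuple(f"mu{i}" for i in range(n_mutants)),
        tuple(f"mk{j}" for j in range(n_markers)),
        states,
    )


def brute_path_cost(m: DeletionMatrix, order, opt: str) -> int:
    """Break count by literal definition: walk each mutant's states."""
    total = 0
    cols = {name: j for j, name in enumerate(m.marker_names)}
    for row in m.states:
        seq = [1] + [int(row[cols[name]]) for name in order]
        if opt == "del":
            seq.append(0)
        total += sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    return total


def brute_force_solve(m: DeletionMatrix, opt: str):
    """Minimum break count and the exact set of optimal permutations."""
    best = None
    orders = []
    for perm in permutations(m.marker_names):
        c = brute_path_cost(m, perm, opt)
        if best is None or c < best:
            best = c
            orders = [perm]
        elif c == best:
            orders.append(perm)
    return best, set(orders)


@pytest.fixture
def tiny_matrix() -> DeletionMatrix:
    """Three markers, one mutant with states (1, 0, 1)."""
    return DeletionMatrix(("mu0",), ("A", "B", "C"), np.array([[1, 0, 1]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
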