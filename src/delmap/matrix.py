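"""Deletion matrices: the mutant-by-marker presence/absence tables.

A deletion matrix records, for a panel of deletion mutants, which markers
are still present (1) and which have been lost (0).  It is the universal
input of the mapping pipeline.  On disk it is delimited text: the first row
holds marker names (with an empty leading field), the first column mutant
names, and every body cell is the literal character ``0`` or ``1``.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DeletionMatrix",
    "PhenotypeCall",
    "PHENOTYPES",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "merge_matrices",
    "encode_phenotypes",
]


class MatrixFormatError(ValueError):
    """Raised for malformed or inconsistent deletion-matrix input."""


@dataclass(frozen=True)
class DeletionMatrix:
    """A validated mutant-by-marker 0/1 matrix.

    Parameters
    ----------
    mutant_names:
        Row labels, unique, at least one.
    marker_names:
        Column labels, unique, at least two.
    states:
        ``(n_mutants, n_markers)`` array of 0 (deleted) / 1 (present).
    """

    mutant_names: tuple[str, ...]
    marker_names: tuple[str, ...]
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutant_names", tuple(self.mutant_names))
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 2:
            raise MatrixFormatError("states must be a 2-D grid")
        object.__setattr__(self, "states", states)
        mu, ma = states.shape
        if mu != len(self.mutant_names) or ma != len(self.marker_names):
            raise MatrixFormatError(
                f"grid is {mu}x{ma} but there are {len(self.mutant_names)} "
                f"mutant and {len(self.marker_names)} marker names"
            )
        if mu < 1:
            raise MatrixFormatError("need at least one mutant")
        if ma < 2:
            raise MatrixFormatError("need at least two markers")
        if len(set(self.mutant_names)) != mu:
            raise MatrixFormatError("duplicate mutant names")
        if len(set(self.marker_names)) != ma:
            raise MatrixFormatError("duplicate marker names")
        bad = (states != 0) & (states != 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"cell ({self.mutant_names[r]}, {self.marker_names[c]}) "
                f"is {states[r, c]}, expected 0 or 1"
            )
        states.setflags(write=False)

    @property
    def n_mutants(self) -> int:
        return len(self.mutant_names)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        """The 0/1 profile of one marker across mutants."""
        return self.states[:, self.marker_index(name)]

    def reorder_markers(self, order: Sequence[str]) -> "DeletionMatrix":
        """Return a copy with marker columns permuted into ``order``."""
        if sorted(order) != sorted(self.marker_names):
            raise MatrixFormatError("order is not a permutation of the markers")
        idx = [self.marker_names.index(n) for n in order]
        return DeletionMatrix(self.mutant_names, tuple(order), self.states[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeletionMatrix):
            return NotImplemented
        return (
            self.mutant_names == other.mutant_names
            and self.marker_names == other.marker_names
            and np.array_equal(self.states, other.states)
        )


PHENOTYPES = (
    "hermaphrodite",
    "asexual",
    "female_like",
    "non_maturing_anthers",
    "male",
)

# (GSF, SPF) states implied by each flower phenotype: loss of the
# gynoecium-suppressing function feminises, loss of the stamen-promoting
# function gives asexual flowers, and a female-like mutant lacks both.
_PHENOTYPE_STATES = {
    "hermaphrodite": (0, 1),
    "asexual": (1, 0),
    "female_like": (0, 0),
    "non_maturing_anthers": (1, 1),
    "male": (1, 1),
}


@dataclass(frozen=True)
class PhenotypeCall:
    """A flower-phenotype observation for one mutant."""

    mutant_name: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_matrix(path: str | os.PathLike, delimiter: str | None = None) -> DeletionMatrix:
    """Read a deletion matrix from delimited text.

    The delimiter is auto-detected between tab and comma unless given.
    Cells must be the literal characters ``0`` or ``1``; anything else is a
    :class:`MatrixFormatError` naming the offending row and column.
    """
    with open(path, "r", newline="") as fh:
        text = fh.read()
    return loads_matrix(text, delimiter=delimiter)


def loads_matrix(text: str, delimiter: str | None = None) -> DeletionMatrix:
    """Parse matrix text (see :func:`read_matrix`)."""
    lines = text.splitlines()
    if not lines:
        raise MatrixFormatError("empty matrix file")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if r]  # drop blank trailing lines
    header = rows[0]
    marker_names = [f.strip() for f in header[1:]]
    width = len(header)
    mutant_names: list[str] = []
    body: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixFormatError(
                f"line {lineno}: expected {width} fields, found {len(row)}"
            )
        mutant = row[0].strip()
        mutant_names.append(mutant)
        states_row = []
        for col, cell in zip(marker_names, row[1:]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise MatrixFormatError(
                    f"cell (mutant {mutant!r}, marker {col!r}) is {cell!r}, "
                    "expected 0 or 1"
                )
            states_row.append(int(cell))
        body.append(states_row)
    return DeletionMatrix(tuple(mutant_names), tuple(marker_names), np.array(body))


def dumps_matrix(m: DeletionMatrix, delimiter: str = ",") -> str:
    out = io.StringIO()
    w = csv.writer(out, delimiter=delimiter, lineterminator="\n")
    w.writerow([""] + list(m.marker_names))
    for name, row in zip(m.mutant_names, m.states):
        w.writerow([name] + [str(int(v)) for v in row])
    return out.getvalue()


def write_matrix(m: DeletionMatrix, path: str | os.PathLike, delimiter: str = ",") -> None:
    """Write ``m`` in the delimited layout accepted by :func:`read_matrix`."""
    with open(path, "w", newline="") as fh:
        fh.write(dumps_matrix(m, delimiter=delimiter))


def read_phenotypes(path: str | os.PathLike, delimiter: str | None = None) -> list[PhenotypeCall]:
    """Read two-column (mutant, phenotype) delimited text."""
    with open(path, "r", newline="") as fh:
        text = fh.read()
    if delimiter is None:
        delimiter = _detect_delimiter(text.splitlines()[0] if text else "")
    calls = []
    for lineno, row in enumerate(csv.reader(io.StringIO(text), delimiter=delimiter), 1):
        if not row:
            continue
        if len(row) != 2:
            raise MatrixFormatError(f"line {lineno}: expected 2 fields, found {len(row)}")
        calls.append(PhenotypeCall(row[0].strip(), row[1].strip()))
    return calls


def merge_matrices(matrices: Sequence[DeletionMatrix]) -> DeletionMatrix:
    """Stack matrices from different experiments over an identical marker set.

    Columns are aligned by marker name to the first input's order; mutant
    names must be disjoint across inputs.  Marker sets that differ are a
    hard error (a missing genotype is not "present").
    """
    if not matrices:
        raise ValueError("nothing to merge")
    first = matrices[0]
    ref = set(first.marker_names)
    for m in matrices[1:]:
        if set(m.marker_names) != ref:
            diff = sorted(ref.symmetric_difference(m.marker_names))
            raise MatrixFormatError(
                "marker sets differ between matrices; not shared: " + ", ".join(diff)
            )
    mutant_names: list[str] = []
    blocks = []
    for m in matrices:
        idx = [m.marker_names.index(n) for n in first.marker_names]
        blocks.append(m.states[:, idx])
        mutant_names.extend(m.mutant_names)
    if len(set(mutant_names)) != len(mutant_names):
        dup = sorted({n for n in mutant_names if mutant_names.count(n) > 1})
        raise MatrixFormatError("duplicate mutant names across inputs: " + ", ".join(dup))
    return DeletionMatrix(tuple(mutant_names), first.marker_names, np.vstack(blocks))


def encode_phenotypes(
    m: DeletionMatrix,
    calls: Iterable[PhenotypeCall],
    gsf_name: str = "GSF",
    spf_name: str = "SPF",
) -> DeletionMatrix:
    """Append the two sex-determining loci as phenotype-derived marker columns.

    Hermaphroditic mutants are scored as having lost GSF, asexual mutants as
    having lost SPF, a female-like mutant as having lost both; mutants with
    non-maturing anthers and male plants keep both.  Mutants without a call
    keep both loci present.
    """
    for name in (gsf_name, spf_name):
        if name in m.marker_names:
            raise MatrixFormatError(f"marker name {name!r} already present")
    gsf = np.ones(m.n_mutants, dtype=np.int8)
    spf = np.ones(m.n_mutants, dtype=np.int8)
    for call in calls:
        if call.mutant_name not in m.mutant_names:
            raise MatrixFormatError(f"unknown mutant {call.mutant_name!r} in phenotype calls")
        i = m.mutant_names.index(call.mutant_name)
        gsf[i], spf[i] = _PHENOTYPE_STATES[call.phenotype]
    states = np.column_stack([m.states, gsf, spf])
    return DeletionMatrix(m.mutant_names, m.marker_names + (gsf_name, spf_name), states)
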