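"""Dyadic counts and simple-ratio-index association matrices.

Counting is at the sampling-period level by default: within one period an
individual is "observed" iff it appears in at least one group, and a dyad
"co-occurs" iff some single group of that period contains both.  Per-bin
(group-level) counting, where every bin is its own sampling unit, is
available via ``unit="bin"``.

For an unordered dyad (A, B) over ``n`` sampling units the counts are

- ``x``     : units where A and B co-occurred in a group,
- ``y_AB``  : units where both were observed but never together,
- ``y_A``   : units where only A was observed,
- ``y_B``   : units where only B was observed,

and the simple ratio index is ``x / (x + y_AB + y_A + y_B)``, in [0, 1].
Dyads whose denominator is zero (neither member ever observed) get weight 0
and are flagged unsampled so matrices stay dense for matrix correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from socnet.grouping import SamplingPeriodTable
from socnet.io_telemetry import ValidationError

__all__ = [
    "AssociationMatrix",
    "DyadCounts",
    "align_individuals",
    "dyad_counts",
    "simple_ratio_index",
    "weighted_degree",
    "write_dyad_table",
]


@dataclass(frozen=True)
class DyadCounts:
    """Symmetric dyadic count arrays over a fixed individual index.

    ``x[i, j]`` is the co-occurrence count, ``both[i, j]`` the number of units
    where both were observed (so ``y_AB = both - x``), ``n_obs[i]`` the number
    of units where i was observed, and ``n_units`` the total number of
    sampling units.  ``y_A`` for dyad (i, j) is ``n_obs[i] - both[i, j]``.
    """

    index: tuple[str, ...]
    x: np.ndarray
    both: np.ndarray
    n_obs: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        n = len(self.index)
        if self.x.shape != (n, n) or self.both.shape != (n, n):
            raise ValidationError("count matrices must be n x n")
        if np.any(self.x > self.both):
            raise ValidationError("x cannot exceed both-observed count")
        if np.any(self.both > np.minimum.outer(self.n_obs, self.n_obs)):
            raise ValidationError("both-observed cannot exceed min(n_obs)")

    def counts_for(self, a: str, b: str) -> tuple[int, int, int, int]:
        """Return (x, y_AB, y_A, y_B) for the ordered pair (a, b)."""
        i, j = self.index.index(a), self.index.index(b)
        x = int(self.x[i, j])
        y_ab = int(self.both[i, j]) - x
        y_a = int(self.n_obs[i]) - int(self.both[i, j])
        y_b = int(self.n_obs[j]) - int(self.both[i, j])
        return x, y_ab, y_a, y_b


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric individual-by-individual edge-weight matrix in [0, 1]."""

    index: tuple[str, ...]
    values: np.ndarray
    counts: DyadCounts | None = None
    unsampled: np.ndarray | None = None  # boolean mask of zero-denominator dyads
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape must match index length")
        if n:
            if not np.allclose(self.values, self.values.T):
                raise ValidationError("association matrix must be symmetric")
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValidationError("association values must lie in [0, 1]")
            if np.any(np.diag(self.values) != 0.0):
                raise ValidationError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.index)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle values as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def edge(self, a: str, b: str) -> float:
        return float(self.values[self.index.index(a), self.index.index(b)])

    def reindex(self, index: Sequence[str]) -> "AssociationMatrix":
        """Subset/reorder to ``index`` (must be a subset of the current one)."""
        pos = [self.index.index(i) for i in index]
        sub = self.values[np.ix_(pos, pos)]
        counts = None
        if self.counts is not None:
            counts = DyadCounts(
                index=tuple(index),
                x=self.counts.x[np.ix_(pos, pos)],
                both=self.counts.both[np.ix_(pos, pos)],
                n_obs=self.counts.n_obs[pos],
                n_units=self.counts.n_units,
            )
        unsampled = None if self.unsampled is None else self.unsampled[np.ix_(pos, pos)]
        return AssociationMatrix(
            index=tuple(index),
            values=sub,
            counts=counts,
            unsampled=unsampled,
            provenance=dict(self.provenance),
        )


def _counts_from_unit_lists(
    unit_members: Sequence[Sequence[frozenset[int] | set[int]]], n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accumulate (x, both, n_obs) from per-unit lists of index-coded groups."""
    x = np.zeros((n, n), dtype=np.int64)
    both = np.zeros((n, n), dtype=np.int64)
    n_obs = np.zeros(n, dtype=np.int64)
    occ = np.zeros(n, dtype=bool)
    co = np.zeros((n, n), dtype=bool)
    for groups in unit_members:
        occ[:] = False
        co[:] = False
        for members in groups:
            idx = np.fromiter(members, dtype=np.intp, count=len(members))
            occ[idx] = True
            if len(idx) > 1:
                co[np.ix_(idx, idx)] = True
        n_obs += occ
        both += np.outer(occ, occ)
        x += co
    np.fill_diagonal(x, 0)
    np.fill_diagonal(both, 0)
    return x, both, n_obs


def dyad_counts(
    periods: SamplingPeriodTable,
    individuals: Sequence[str] | None = None,
    unit: str = "period",
) -> DyadCounts:
    """Tally dyadic counts over sampling units.

    ``unit="period"`` (default) scores each sampling period once per dyad;
    ``unit="bin"`` treats every (receiver, bin) group's bin as its own unit.
    """
    if unit not in ("period", "bin"):
        raise ValidationError(f"unit must be 'period' or 'bin', got {unit!r}")
    index = tuple(individuals) if individuals is not None else periods.individuals()
    pos = {iid: i for i, iid in enumerate(index)}
    for groups in periods.periods.values():
        for g in groups:
            unknown = g.members - pos.keys()
            if unknown:
                raise ValidationError(
                    f"group members {sorted(unknown)} missing from individual index"
                )
    unit_lists: list[list[set[int]]] = []
    if unit == "period":
        for key in sorted(periods.periods):
            unit_lists.append(
                [{pos[m] for m in g.members} for g in periods.periods[key]]
            )
    else:
        bins: dict[float, list[set[int]]] = {}
        for groups in periods.periods.values():
            for g in groups:
                bins.setdefault(g.bin_start, []).append({pos[m] for m in g.members})
        unit_lists = [bins[k] for k in sorted(bins)]
    x, both, n_obs = _counts_from_unit_lists(unit_lists, len(index))
    return DyadCounts(index=index, x=x, both=both, n_obs=n_obs, n_units=len(unit_lists))


def simple_ratio_index(
    counts: DyadCounts, provenance: Mapping[str, object] | None = None
) -> AssociationMatrix:
    """Build the simple-ratio-index matrix ``x / (x + y_AB + y_A + y_B)``.

    The denominator simplifies to ``n_obs_A + n_obs_B - both_AB``.  Endpoints:
    1 when the dyad shares a group in every unit where either is observed, 0
    when both are observed but never together.
    """
    n = len(counts.index)
    denom = counts.n_obs[:, None] + counts.n_obs[None, :] - counts.both
    unsampled = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(unsampled, 0.0, counts.x / np.where(unsampled, 1, denom))
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(unsampled, False)
    return AssociationMatrix(
        index=counts.index,
        values=values,
        counts=counts,
        unsampled=unsampled,
        provenance=dict(provenance or {}),
    )


def weighted_degree(matrix: AssociationMatrix) -> np.ndarray:
    """Per-individual strength: the row sums of the association matrix."""
    return matrix.values.sum(axis=1)


def write_dyad_table(matrix: AssociationMatrix, path) -> None:
    """Export per-dyad counts and index: a, b, x, y_ab, y_a, y_b, sri."""
    import csv
    from pathlib import Path

    if matrix.counts is None:
        raise ValidationError("matrix carries no dyad counts")
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["a", "b", "x", "y_ab", "y_a", "y_b", "sri"])
        for i, a in enumerate(matrix.index):
            for b in matrix.index[i + 1:]:
                x, y_ab, y_a, y_b = matrix.counts.counts_for(a, b)
                writer.writerow([a, b, x, y_ab, y_a, y_b, repr(matrix.edge(a, b))])


def align_individuals(
    matrices: Sequence[AssociationMatrix],
) -> list[AssociationMatrix]:
    """Restrict matrices to the sorted intersection of their individual sets."""
    if len(matrices) < 2:
        raise ValidationError("need at least two matrices to align")
    common: set[str] = set(matrices[0].index)
    for m in matrices[1:]:
        common &= set(m.index)
    if not common:
        raise ValidationError("no individuals common to all matrices")
    index = sorted(common)
    return [m.reindex(index) for m in matrices]
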