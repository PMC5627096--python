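"""Data-stream permutations of group data and non-randomness tests.

The null model serially swaps individuals between observed groups.  One swap
exchanges ``a in g1 - g2`` with ``b in g2 - g1`` for two eligible groups
(same sampling period by default), so group sizes and every individual's
total number of group memberships are exactly conserved; with the
within-period constraint the per-period "times observed" vector is conserved
too, making the tests sensitive to association structure rather than
sampling effort.

A single evolving copy of the data is mutated; after every
``swaps_between_samples`` swaps the association matrix is rebuilt and each
requested statistic recorded.  Significance uses the add-one rule
``p = (1 + #{null >= obs}) / (1 + n)`` so p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from socnet.association import (
    AssociationMatrix,
    DyadCounts,
    _counts_from_unit_lists,
    simple_ratio_index,
)
from socnet.grouping import GroupObservation, SamplingPeriodTable
from socnet.io_telemetry import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupData",
    "NonrandomnessSummary",
    "NullDistribution",
    "SwapConstraint",
    "cv_association",
    "matrix_from_group_data",
    "mean_association",
    "nonrandomness_test",
    "permuted_null_stream",
    "swap_once",
]


@dataclass(frozen=True)
class SwapConstraint:
    """Which group pairs are eligible for a swap."""

    within_period: bool = True
    within_receiver: bool = False
    max_retries: int = 100


@dataclass
class GroupData:
    """Mutable, index-coded group-by-period data for swap chains."""

    index: tuple[str, ...]
    period_of: list[int]  # per group, index into period_keys
    receiver_of: list[str]
    bin_start_of: list[float]
    members: list[set[int]]  # per group, set of individual indices
    period_keys: list[float]
    period_width: float

    @classmethod
    def from_periods(
        cls, periods: SamplingPeriodTable, individuals: Sequence[str] | None = None
    ) -> "GroupData":
        index = tuple(individuals) if individuals is not None else periods.individuals()
        pos = {iid: i for i, iid in enumerate(index)}
        keys = sorted(periods.periods)
        period_of: list[int] = []
        receiver_of: list[str] = []
        bin_start_of: list[float] = []
        members: list[set[int]] = []
        for p, key in enumerate(keys):
            for g in periods.periods[key]:
                unknown = g.members - pos.keys()
                if unknown:
                    raise ValidationError(
                        f"group members {sorted(unknown)} missing from index"
                    )
                period_of.append(p)
                receiver_of.append(g.receiver_id)
                bin_start_of.append(g.bin_start)
                members.append({pos[m] for m in g.members})
        return cls(
            index=index,
            period_of=period_of,
            receiver_of=receiver_of,
            bin_start_of=bin_start_of,
            members=members,
            period_keys=keys,
            period_width=periods.period_width,
        )

    def to_periods(self) -> SamplingPeriodTable:
        table: dict[float, list[GroupObservation]] = {k: [] for k in self.period_keys}
        for p, rid, start, mem in zip(
            self.period_of, self.receiver_of, self.bin_start_of, self.members
        ):
            table[self.period_keys[p]].append(
                GroupObservation(rid, start, frozenset(self.index[i] for i in mem))
            )
        return SamplingPeriodTable(
            period_width=self.period_width,
            periods={k: tuple(v) for k, v in table.items() if v},
        )

    def copy(self) -> "GroupData":
        return GroupData(
            index=self.index,
            period_of=list(self.period_of),
            receiver_of=list(self.receiver_of),
            bin_start_of=list(self.bin_start_of),
            members=[set(m) for m in self.members],
            period_keys=list(self.period_keys),
            period_width=self.period_width,
        )

    def membership_counts(self) -> np.ndarray:
        counts = np.zeros(len(self.index), dtype=np.int64)
        for mem in self.members:
            for i in mem:
                counts[i] += 1
        return counts

    def group_sizes(self) -> list[int]:
        return sorted(len(m) for m in self.members)

    def eligible_pairs(self, constraint: SwapConstraint) -> list[tuple[int, int]]:
        """All unordered pairs of distinct groups satisfying the constraint."""
        blocks: dict[tuple, list[int]] = {}
        for g in range(len(self.members)):
            key: tuple = ()
            if constraint.within_period:
                key += (self.period_of[g],)
            if constraint.within_receiver:
                key += (self.receiver_of[g],)
            blocks.setdefault(key, []).append(g)
        pairs: list[tuple[int, int]] = []
        for ids in blocks.values():
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    pairs.append((ids[i], ids[j]))
        return pairs


def swap_once(
    data: GroupData,
    constraint: SwapConstraint | None = None,
    rng: np.random.Generator | None = None,
    eligible_pairs: Sequence[tuple[int, int]] | None = None,
) -> bool:
    """Perform one individual swap in place; return True if data changed.

    A pair of eligible groups is drawn uniformly, then ``a in g1 - g2`` and
    ``b in g2 - g1`` uniformly; a and b are exchanged.  Pairs with no valid
    (a, b) are redrawn up to ``constraint.max_retries`` times; if none is
    found the data is returned unchanged and False is reported.
    """
    constraint = constraint or SwapConstraint()
    rng = rng if rng is not None else np.random.default_rng()
    pairs = eligible_pairs if eligible_pairs is not None else data.eligible_pairs(constraint)
    if not pairs:
        return False
    for _ in range(max(1, constraint.max_retries)):
        g1, g2 = pairs[int(rng.integers(len(pairs)))]
        m1, m2 = data.members[g1], data.members[g2]
        only1 = sorted(m1 - m2)
        only2 = sorted(m2 - m1)
        if not only1 or not only2:
            continue
        a = only1[int(rng.integers(len(only1)))]
        b = only2[int(rng.integers(len(only2)))]
        m1.remove(a)
        m1.add(b)
        m2.remove(b)
        m2.add(a)
        return True
    logger.debug("no valid swap found; returning data unchanged")
    return False


def matrix_from_group_data(data: GroupData, unit: str = "period") -> AssociationMatrix:
    """Rebuild the simple-ratio-index matrix from (possibly permuted) groups."""
    n = len(data.index)
    if unit == "period":
        unit_lists: list[list[set[int]]] = [[] for _ in data.period_keys]
        for p, mem in zip(data.period_of, data.members):
            unit_lists[p].append(mem)
    elif unit == "bin":
        bins: dict[float, list[set[int]]] = {}
        for start, mem in zip(data.bin_start_of, data.members):
            bins.setdefault(start, []).append(mem)
        unit_lists = [bins[k] for k in sorted(bins)]
    else:
        raise ValidationError(f"unit must be 'period' or 'bin', got {unit!r}")
    x, both, n_obs = _counts_from_unit_lists(unit_lists, n)
    counts = DyadCounts(
        index=data.index, x=x, both=both, n_obs=n_obs, n_units=len(unit_lists)
    )
    return simple_ratio_index(counts)


def mean_association(matrix: AssociationMatrix) -> float:
    """Mean of the off-diagonal dyad weights (zeros included)."""
    return float(matrix.upper_triangle().mean())


def cv_association(matrix: AssociationMatrix) -> float:
    """Coefficient of variation (sample sd / mean) of the dyad weights."""
    tri = matrix.upper_triangle()
    mean = tri.mean()
    if mean == 0:
        return float("nan")
    return float(tri.std(ddof=1) / mean)


BUILTIN_STATISTICS: Mapping[str, Callable[[AssociationMatrix], float]] = {
    "mean": mean_association,
    "cv": cv_association,
}


@dataclass(frozen=True)
class NullDistribution:
    """Null statistics from a serial swap chain, plus the observed value."""

    statistic: str
    values: np.ndarray
    observed: float
    direction: str
    p: float

    @property
    def n_permutations(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        """Single-column audit export of the null values."""
        from pathlib import Path

        lines = [self.statistic] + [repr(float(v)) for v in self.values]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class NonrandomnessSummary:
    statistic: str
    observed: float
    null_mean: float
    null_lo: float  # 2.5th percentile
    null_hi: float  # 97.5th percentile
    p: float
    direction: str


def _add_one_p(observed: float, null_values: np.ndarray, direction: str) -> float:
    if direction == "greater":
        extreme = int(np.sum(null_values >= observed))
    elif direction == "less":
        extreme = int(np.sum(null_values <= observed))
    else:
        raise ValidationError(f"direction must be 'greater' or 'less', got {direction!r}")
    return (1 + extreme) / (1 + len(null_values))


def permuted_null_stream(
    periods: SamplingPeriodTable,
    n_permutations: int = 10_000,
    swaps_between_samples: int = 1,
    constraint: SwapConstraint | None = None,
    seed: int | np.random.Generator | None = None,
    statistics: Mapping[str, Callable[[AssociationMatrix], float]] | None = None,
    individuals: Sequence[str] | None = None,
    unit: str = "period",
    direction: str = "greater",
) -> dict[str, NullDistribution]:
    """Serial swap chain: mutate one copy of the data, sample statistics.

    Returns one :class:`NullDistribution` per requested statistic (default:
    mean and CV of the association indices), each carrying the observed value
    and its add-one permutation p-value.
    """
    if n_permutations <= 0:
        raise ValidationError("n_permutations must be > 0")
    if not periods.periods:
        raise ValidationError("empty sampling-period table")
    constraint = constraint or SwapConstraint()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats = dict(statistics or BUILTIN_STATISTICS)

    data = GroupData.from_periods(periods, individuals)
    pairs = data.eligible_pairs(constraint)
    observed_matrix = matrix_from_group_data(data, unit=unit)
    observed = {name: fn(observed_matrix) for name, fn in stats.items()}

    sampled = {name: np.empty(n_permutations) for name in stats}
    for k in range(n_permutations):
        for _ in range(swaps_between_samples):
            swap_once(data, constraint, rng, eligible_pairs=pairs)
        matrix = matrix_from_group_data(data, unit=unit)
        for name, fn in stats.items():
            sampled[name][k] = fn(matrix)

    out: dict[str, NullDistribution] = {}
    for name in stats:
        out[name] = NullDistribution(
            statistic=name,
            values=sampled[name],
            observed=observed[name],
            direction=direction,
            p=_add_one_p(observed[name], sampled[name], direction),
        )
    return out


def nonrandomness_test(
    observed: float | AssociationMatrix,
    null: NullDistribution,
    direction: str = "greater",
) -> NonrandomnessSummary:
    """Compare an observed statistic against its permutation null."""
    if len(null.values) == 0:
        raise ValidationError("null distribution is empty")
    if isinstance(observed, AssociationMatrix):
        try:
            observed_value = BUILTIN_STATISTICS[null.statistic](observed)
        except KeyError:
            raise ValidationError(
                f"no builtin statistic named {null.statistic!r}; pass a float"
            ) from None
    else:
        observed_value = float(observed)
    return NonrandomnessSummary(
        statistic=null.statistic,
        observed=observed_value,
        null_mean=float(np.mean(null.values)),
        null_lo=float(np.percentile(null.values, 2.5)),
        null_hi=float(np.percentile(null.values, 97.5)),
        p=_add_one_p(observed_value, null.values, direction),
        direction=direction,
    )
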