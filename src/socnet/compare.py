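"""Between-network comparisons.

Two complementary questions about a pair of association matrices built from
the same population:

- do the dyadic weights agree?  Answered by a Mantel test: Pearson
  correlation of the vectorized strict upper triangles, with a null built by
  jointly relabelling rows and columns of the second matrix.
- do individuals keep their network position?  Answered by the
  sum-of-variances statistic on scaled weighted-degree ranks: each
  individual's rank (average-rank ties, scaled to [0, 1]) is tracked across
  networks; SV is the sum over individuals of the sample variance of those
  ranks.  Small SV means consistent position, so the permutation p-value
  counts null SV values <= the observed one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from socnet.association import AssociationMatrix, align_individuals, weighted_degree
from socnet.grouping import SamplingPeriodTable
from socnet.io_telemetry import ValidationError
from socnet.randomization import (
    GroupData,
    SwapConstraint,
    _add_one_p,
    matrix_from_group_data,
    swap_once,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConsistencyResult",
    "MantelResult",
    "consistency_test",
    "mantel_test",
    "scaled_degree_ranks",
    "sum_of_variances",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    n_individuals: int
    direction: str


@dataclass(frozen=True)
class ConsistencyResult:
    sv_observed: float
    sv_null: np.ndarray
    null_mean: float
    null_lo: float  # 2.5th percentile
    null_hi: float  # 97.5th percentile
    p: float
    n_permutations: int
    n_individuals: int
    # both group datasets are permuted by independent swap chains; the
    # interval is the central 95% of the null SV values
    randomized: str = "both"
    interval: str = "percentile-2.5/97.5"


def _triangle_correlation(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        raise ValidationError("zero variance in a matrix triangle: Mantel r undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def mantel_test(
    m1: AssociationMatrix,
    m2: AssociationMatrix,
    n_permutations: int = 999,
    direction: str = "greater",
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel correlation between two aligned association matrices.

    ``exact=True`` enumerates all n! relabellings instead of sampling (only
    sensible for very small n); the add-one p-value then counts the identity
    relabelling via the enumeration itself.
    """
    if m1.index != m2.index:
        raise ValidationError("matrices must share an identical individual index")
    n = m1.n
    if n < 3:
        raise ValidationError("Mantel test requires at least 3 individuals")
    r_obs = _triangle_correlation(m1.values, m2.values)

    if exact:
        null = np.array(
            [
                _triangle_correlation(m1.values, m2.values[np.ix_(p, p)])
                for p in itertools.permutations(range(n))
            ]
        )
        if direction == "greater":
            p_val = float(np.mean(null >= r_obs - 1e-12))
        elif direction == "less":
            p_val = float(np.mean(null <= r_obs + 1e-12))
        else:
            raise ValidationError(f"bad direction {direction!r}")
        return MantelResult(
            r=r_obs, p=p_val, n_permutations=len(null), n_individuals=n,
            direction=direction,
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = rng.permutation(n)
        null[k] = _triangle_correlation(m1.values, m2.values[np.ix_(perm, perm)])
    return MantelResult(
        r=r_obs,
        p=_add_one_p(r_obs, null, direction),
        n_permutations=n_permutations,
        n_individuals=n,
        direction=direction,
    )


def scaled_degree_ranks(matrix: AssociationMatrix) -> np.ndarray:
    """Rank individuals by weighted degree and scale ranks to [0, 1].

    Ascending ranks, average ranks on ties, scaled as (rank - 1) / (n - 1).
    """
    n = matrix.n
    if n < 2:
        raise ValidationError("ranking requires at least 2 individuals")
    ranks = rankdata(weighted_degree(matrix), method="average")
    return (ranks - 1.0) / (n - 1.0)


def sum_of_variances(rank_vectors: np.ndarray) -> float:
    """Sum over individuals of the sample variance of their scaled rank.

    ``rank_vectors`` is (n_networks, n_individuals); with two networks each
    individual contributes ``(a - b)**2 / 2``.
    """
    vectors = np.asarray(rank_vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValidationError("need >= 2 aligned rank vectors")
    return float(np.var(vectors, axis=0, ddof=1).sum())


def consistency_test(
    periods_1: SamplingPeriodTable,
    periods_2: SamplingPeriodTable,
    n_permutations: int = 10_000,
    swaps_between_samples: int = 1,
    constraint: SwapConstraint | None = None,
    seed: int | np.random.Generator | None = None,
    unit: str = "period",
) -> ConsistencyResult:
    """Rank-consistency test between two group datasets.

    Both datasets are permuted by independent serial swap chains; after each
    sampling step both matrices are rebuilt on the common individual index and
    the sum of rank variances recomputed.  Low p-values indicate that the
    observed SV is smaller than expected at random, i.e. individuals keep
    their relative network position across the two datasets.
    """
    if n_permutations <= 0:
        raise ValidationError("n_permutations must be > 0")
    constraint = constraint or SwapConstraint()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    common = sorted(set(periods_1.individuals()) & set(periods_2.individuals()))
    if len(common) < 2:
        raise ValidationError("datasets share fewer than 2 individuals")

    d1 = GroupData.from_periods(periods_1)
    d2 = GroupData.from_periods(periods_2)
    pairs1 = d1.eligible_pairs(constraint)
    pairs2 = d2.eligible_pairs(constraint)
    if not pairs1 or not pairs2:
        logger.warning("degenerate data: no eligible swap pairs; null collapses")

    def sv_of(a: GroupData, b: GroupData) -> float:
        ma = matrix_from_group_data(a, unit=unit).reindex(common)
        mb = matrix_from_group_data(b, unit=unit).reindex(common)
        return sum_of_variances(
            np.vstack([scaled_degree_ranks(ma), scaled_degree_ranks(mb)])
        )

    sv_obs = sv_of(d1, d2)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        for _ in range(swaps_between_samples):
            swap_once(d1, constraint, rng, eligible_pairs=pairs1)
            swap_once(d2, constraint, rng, eligible_pairs=pairs2)
        null[k] = sv_of(d1, d2)

    return ConsistencyResult(
        sv_observed=sv_obs,
        sv_null=null,
        null_mean=float(null.mean()),
        null_lo=float(np.percentile(null, 2.5)),
        null_hi=float(np.percentile(null, 97.5)),
        p=_add_one_p(sv_obs, null, "less"),
        n_permutations=n_permutations,
        n_individuals=len(common),
    )
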