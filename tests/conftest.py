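"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from socnet.grouping import GroupObservation, SamplingPeriodTable

PERIOD = 3600.0
BIN = 600.0


def make_periods(spec: dict[int, list[set[str]]]) -> SamplingPeriodTable:
    """Build a period table from {period index: [member sets, ...]}.

    Groups within a period are laid out in consecutive bins of one receiver.
    """
    periods: dict[float, tuple[GroupObservation, ...]] = {}
    for p, member_sets in spec.items():
        start = p * PERIOD
        groups = tuple(
            GroupObservation("R", start + (i % 6) * BIN, frozenset(m))
            for i, m in enumerate(member_sets)
        )
        periods[start] = groups
    return SamplingPeriodTable(period_width=PERIOD, periods=periods)


def brute_force_sri(spec: dict[int, list[set[str]]]) -> tuple[list[str], np.ndarray]:
    """Literal period/dyad enumeration of the simple ratio index.

    Independent of the pipeline: plain Python loops over periods and dyads,
    following the printed count definitions verbatim.
    """
    individuals = sorted({m for groups in spec.values() for g in groups for m in g})
    n = len(individuals)
    matrix = np.zeros((n, n))
    for i, a in enumerate(individuals):
        for j, b in enumerate(individuals):
            if i >= j:
                continue
            x = y_ab = y_a = y_b = 0
            for groups in spec.values():
                seen_a = any(a in g for g in groups)
                seen_b = any(b in g for g in groups)
                together = any(a in g and b in g for g in groups)
                if together:
                    x += 1
                elif seen_a and seen_b:
                    y_ab += 1
                elif seen_a:
                    y_a += 1
                elif seen_b:
                    y_b += 1
            denom = x + y_ab + y_a + y_b
            value = x / denom if denom else 0.0
            matrix[i, j] = matrix[j, i] = value
    return individuals, matrix


def random_period_spec(
    rng: np.random.Generator,
    n_individuals: int = 10,
    n_periods: int = 30,
) -> dict[int, list[set[str]]]:
    """Random small group data for oracle-equivalence checks."""
    ids = [f"I{k}" for k in range(rng.integers(2, n_individuals + 1))]
    spec: dict[int, list[set[str]]] = {}
    for p in range(int(rng.integers(1, n_periods + 1))):
        groups = []
        for _ in range(int(rng.integers(0, 5))):
            size = int(rng.integers(1, min(4, len(ids)) + 1))
            members = set(rng.choice(ids, size=size, replace=False))
            groups.append(members)
        if groups:
            spec[p] = groups
    if not spec:
        spec[0] = [{ids[0]}]
    return spec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120825)
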