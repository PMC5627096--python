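"""Agent-based generator of trajectories, pings, detections and ground truth.

The movement model is deliberately simple: each individual alternates
exponential-duration rest bouts at discrete sites with straight-line travel
between sites.  At the end of a bout the next site is, with probability
``p_social``, the current site of a partner drawn proportionally to that
individual's preference weights; otherwise a uniformly random site.  Within a
site the resting position is the site centre plus isotropic Gaussian scatter,
drawn once per bout, so co-resting animals form tight, stationary groups.

Tags ping with a fixed nominal delay (optionally jittered uniformly), and a
ping is recorded by a receiver according to a step or logistic function of the
sender-receiver distance relative to the detection radius.  Animal-borne
receivers track their host's position and never record the host's own pings.

Simultaneous-transmission collisions are not modelled.  Everything is
reproducible from ``SimulationConfig.seed``; sub-streams for trajectories,
pings and detections are derived from it so stages can be re-run in
isolation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from socnet.association import AssociationMatrix, dyad_counts, simple_ratio_index
from socnet.grouping import GroupObservation, collapse_to_periods
from socnet.io_telemetry import (
    DetectionRecord,
    IndividualSpec,
    ReceiverSpec,
    ValidationError,
    format_time,
)

__all__ = [
    "PingSeries",
    "SimulationConfig",
    "TrajectorySet",
    "TrueContactLedger",
    "generate_pings",
    "jervis2012_preset",
    "open_array_preset",
    "simulate_detections",
    "simulate_trajectories",
    "blocked_preferences",
    "true_association_matrix",
    "true_contacts",
    "true_groups",
    "write_truth_contacts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the movement / ping / detection generator."""

    n_individuals: int
    duration: float  # seconds
    site_positions: tuple[tuple[float, float], ...]
    preference_matrix: tuple[tuple[float, ...], ...] | None = None
    p_social: float = 0.5
    rest_duration_mean: float = 21_600.0  # 6 h bouts
    site_scatter_sd: float = 3.0
    travel_speed: float = 0.5  # m/s
    step: float = 60.0  # s
    nominal_delay: float = 90.0  # s between pings
    delay_jitter: float = 0.0  # inter-ping interval uniform on nominal*(1 +/- jitter)
    contact_radius: float = 4.0  # m, ground-truth association scale
    detection_model: str = "step"  # "step" | "logistic"
    logistic_midpoint_fraction: float = 1.0
    logistic_steepness: float = 10.0
    p_det_inside: float = 1.0
    seed: int = 0
    t0: float = 0.0  # epoch seconds of simulation start
    individual_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be > 0")
        if len(self.site_positions) == 0:
            raise ValidationError("at least one site is required")
        for name in (
            "rest_duration_mean",
            "travel_speed",
            "step",
            "nominal_delay",
            "contact_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.duration < 0:
            raise ValidationError("duration must be >= 0")
        if not 0.0 <= self.p_social <= 1.0:
            raise ValidationError("p_social must lie in [0, 1]")
        if not 0.0 <= self.delay_jitter < 1.0:
            raise ValidationError("delay_jitter must lie in [0, 1)")
        if not 0.0 <= self.p_det_inside <= 1.0:
            raise ValidationError("p_det_inside must lie in [0, 1]")
        if self.detection_model not in ("step", "logistic"):
            raise ValidationError(f"unknown detection_model {self.detection_model!r}")
        if self.site_scatter_sd < 0:
            raise ValidationError("site_scatter_sd must be >= 0")
        if not self.individual_ids:
            object.__setattr__(
                self,
                "individual_ids",
                tuple(f"S{i + 1:02d}" for i in range(self.n_individuals)),
            )
        if len(self.individual_ids) != self.n_individuals:
            raise ValidationError("individual_ids length must equal n_individuals")
        if self.preference_matrix is not None:
            pref = np.asarray(self.preference_matrix, dtype=float)
            n = self.n_individuals
            if pref.shape != (n, n):
                raise ValidationError("preference_matrix must be n x n")
            if np.any(pref < 0):
                raise ValidationError("preference weights must be >= 0")
            if not np.allclose(pref, pref.T):
                raise ValidationError("preference_matrix must be symmetric")
            if np.any(np.diag(pref) != 0):
                raise ValidationError("preference_matrix diagonal must be zero")

    @property
    def sites(self) -> np.ndarray:
        return np.asarray(self.site_positions, dtype=float)

    @property
    def preferences(self) -> np.ndarray:
        if self.preference_matrix is None:
            return np.zeros((self.n_individuals, self.n_individuals))
        return np.asarray(self.preference_matrix, dtype=float)

    @property
    def n_steps(self) -> int:
        return int(self.duration // self.step)

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage random stream derived from the seed."""
        stage_key = int.from_bytes(stage.encode(), "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))


@dataclass(frozen=True)
class TrajectorySet:
    """Per-individual positions and behavioural state on the step grid."""

    ids: tuple[str, ...]
    t0: float
    step: float
    positions: np.ndarray  # (n_individuals, n_steps, 2)
    states: np.ndarray  # (n_individuals, n_steps): 0 = resting, 1 = travelling

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(self.n_steps)

    def step_index(self, times: np.ndarray) -> np.ndarray:
        idx = np.floor((np.asarray(times) - self.t0) / self.step).astype(np.intp)
        return np.clip(idx, 0, max(self.n_steps - 1, 0))

    def position_at(self, times: np.ndarray, individual_idx: np.ndarray) -> np.ndarray:
        return self.positions[np.asarray(individual_idx, dtype=np.intp),
                              self.step_index(times)]


class PingEvent:
    """One tag transmission."""

    __slots__ = ("individual_id", "time")

    def __init__(self, individual_id: str, time: float) -> None:
        self.individual_id = individual_id
        self.time = time

    def __repr__(self) -> str:  # pragma: no cover
        return f"PingEvent({self.individual_id!r}, {self.time})"


@dataclass(frozen=True)
class PingSeries:
    """All tag transmissions, time-sorted, index-coded for speed."""

    ids: tuple[str, ...]
    individual_index: np.ndarray  # (n_pings,) int
    times: np.ndarray  # (n_pings,) float, ascending

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        for i, t in zip(self.individual_index, self.times):
            yield PingEvent(self.ids[i], float(t))

    def intervals(self, individual_id: str) -> np.ndarray:
        mask = self.individual_index == self.ids.index(individual_id)
        return np.diff(self.times[mask])


@dataclass(frozen=True)
class TrueContactLedger:
    """Per time step, the unordered dyads within the contact radius."""

    ids: tuple[str, ...]
    t0: float
    step: float
    contact_radius: float
    pairs_per_step: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_steps(self) -> int:
        return len(self.pairs_per_step)


def simulate_trajectories(config: SimulationConfig) -> TrajectorySet:
    """Run the rest-bout / site-choice movement model."""
    rng = config.rng("trajectories")
    n, n_steps = config.n_individuals, config.n_steps
    sites = config.sites
    n_sites = len(sites)
    pref = config.preferences
    pref_total = pref.sum(axis=1)

    positions = np.zeros((n, n_steps, 2))
    states = np.zeros((n, n_steps), dtype=np.uint8)

    # state: 0 resting at cur_site, 1 travelling to cur_site
    mode = np.zeros(n, dtype=np.uint8)
    cur_site = rng.integers(n_sites, size=n)
    pos = sites[cur_site] + rng.normal(0.0, config.site_scatter_sd, size=(n, 2))
    target = pos.copy()
    rest_until = config.t0 + rng.exponential(config.rest_duration_mean, size=n)

    step_dist = config.travel_speed * config.step
    for k in range(n_steps):
        t = config.t0 + k * config.step
        for i in range(n):
            if mode[i] == 0 and t >= rest_until[i]:
                if rng.random() < config.p_social and pref_total[i] > 0:
                    j = rng.choice(n, p=pref[i] / pref_total[i])
                    nxt = cur_site[j]
                else:
                    nxt = int(rng.integers(n_sites))
                if nxt == cur_site[i]:
                    # new bout at the same site: shuffle the resting spot
                    pos[i] = sites[nxt] + rng.normal(
                        0.0, config.site_scatter_sd, size=2
                    )
                    rest_until[i] = t + rng.exponential(config.rest_duration_mean)
                else:
                    cur_site[i] = nxt
                    target[i] = sites[nxt] + rng.normal(
                        0.0, config.site_scatter_sd, size=2
                    )
                    mode[i] = 1
            if mode[i] == 1:
                delta = target[i] - pos[i]
                dist = float(np.hypot(delta[0], delta[1]))
                if dist <= step_dist:
                    pos[i] = target[i]
                    mode[i] = 0
                    rest_until[i] = t + rng.exponential(config.rest_duration_mean)
                else:
                    pos[i] = pos[i] + delta * (step_dist / dist)
            positions[i, k] = pos[i]
            states[i, k] = mode[i]

    return TrajectorySet(
        ids=config.individual_ids,
        t0=config.t0,
        step=config.step,
        positions=positions,
        states=states,
    )


def generate_pings(
    trajectories: TrajectorySet, config: SimulationConfig
) -> PingSeries:
    """Emit per-individual ping times on the configured delay schedule.

    The first ping of each tag is uniform on its first inter-ping interval;
    with ``delay_jitter`` 0 all subsequent intervals equal ``nominal_delay``,
    otherwise they are i.i.d. uniform on ``nominal_delay * (1 +/- jitter)``.
    """
    if trajectories.n_steps == 0:
        return PingSeries(trajectories.ids, np.empty(0, np.intp), np.empty(0))
    rng = config.rng("pings")
    t_end = config.t0 + config.duration
    lo = config.nominal_delay * (1.0 - config.delay_jitter)
    hi = config.nominal_delay * (1.0 + config.delay_jitter)

    idx_chunks: list[np.ndarray] = []
    time_chunks: list[np.ndarray] = []
    for i in range(len(trajectories.ids)):
        times: list[float] = []
        interval = lo if config.delay_jitter == 0 else rng.uniform(lo, hi)
        t = config.t0 + rng.uniform(0.0, interval)
        while t < t_end:
            times.append(t)
            interval = lo if config.delay_jitter == 0 else rng.uniform(lo, hi)
            t += interval
        idx_chunks.append(np.full(len(times), i, dtype=np.intp))
        time_chunks.append(np.asarray(times))
    idx = np.concatenate(idx_chunks)
    times_all = np.concatenate(time_chunks)
    order = np.lexsort((idx, times_all))
    return PingSeries(trajectories.ids, idx[order], times_all[order])


def _detection_probability(
    d: np.ndarray, radius: float, config: SimulationConfig
) -> np.ndarray:
    if config.detection_model == "step":
        return np.where(d <= radius, config.p_det_inside, 0.0)
    z = config.logistic_steepness * (d / radius - config.logistic_midpoint_fraction)
    return config.p_det_inside / (1.0 + np.exp(z))


def simulate_detections(
    pings: PingSeries,
    trajectories: TrajectorySet,
    receivers: Sequence[ReceiverSpec],
    config: SimulationConfig,
) -> list[DetectionRecord]:
    """Turn pings into receiver detections via the range model."""
    rng = config.rng("detections")
    records: list[DetectionRecord] = []
    if len(pings) == 0:
        return records
    sender_pos = trajectories.position_at(pings.times, pings.individual_index)
    for receiver in receivers:
        if receiver.kind == "mobile":
            host = receiver.host_individual
            if host not in trajectories.ids:
                raise ValidationError(
                    f"mobile receiver {receiver.receiver_id}: host {host!r} "
                    "has no trajectory"
                )
            host_idx = trajectories.ids.index(host)
            rec_pos = trajectories.position_at(
                pings.times, np.full(len(pings), host_idx, dtype=np.intp)
            )
            not_self = pings.individual_index != host_idx
        else:
            rec_pos = np.array([receiver.x, receiver.y])[None, :]
            not_self = np.ones(len(pings), dtype=bool)
        d = np.hypot(*(sender_pos - rec_pos).T)
        p = _detection_probability(d, receiver.detection_radius, config)
        detected = (rng.random(len(pings)) < p) & not_self
        for k in np.flatnonzero(detected):
            records.append(
                DetectionRecord(
                    float(pings.times[k]),
                    receiver.receiver_id,
                    pings.ids[pings.individual_index[k]],
                )
            )
    records.sort(key=lambda r: (r.time, r.receiver_id, r.individual_id))
    return records


def true_contacts(
    trajectories: TrajectorySet, contact_radius: float
) -> TrueContactLedger:
    """Ground-truth dyads within ``contact_radius`` at every step."""
    n = len(trajectories.ids)
    pairs_per_step: list[tuple[tuple[int, int], ...]] = []
    iu = np.triu_indices(n, k=1)
    for k in range(trajectories.n_steps):
        p = trajectories.positions[:, k, :]
        diff = p[:, None, :] - p[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
        close = d[iu] <= contact_radius
        pairs_per_step.append(
            tuple((int(i), int(j)) for i, j in zip(iu[0][close], iu[1][close]))
        )
    return TrueContactLedger(
        ids=trajectories.ids,
        t0=trajectories.t0,
        step=trajectories.step,
        contact_radius=contact_radius,
        pairs_per_step=tuple(pairs_per_step),
    )


def _components(n: int, pairs: Sequence[tuple[int, int]]) -> list[frozenset[int]]:
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return [frozenset(c) for c in comps.values()]


def true_groups(
    ledger: TrueContactLedger, bin_width: float = 600.0, transitive: bool = True
) -> list[GroupObservation]:
    """Per-step contact groups at the pseudo-receiver ``"truth"``.

    Groups are connected components of the contact graph under
    ``transitive=True`` (the chain rule), or one group per contacting dyad
    otherwise; singletons are kept so every individual counts as observed at
    every step.  Identical (bin, members) groups are emitted once.
    """
    n = len(ledger.ids)
    seen: set[tuple[float, frozenset[int]]] = set()
    groups: list[GroupObservation] = []
    for k, pairs in enumerate(ledger.pairs_per_step):
        t = ledger.t0 + k * ledger.step
        bin_start = (t // bin_width) * bin_width
        if transitive:
            comps = _components(n, pairs)
        else:
            in_pair = {i for ij in pairs for i in ij}
            comps = [frozenset(ij) for ij in pairs] + [
                frozenset({i}) for i in range(n) if i not in in_pair
            ]
        for comp in comps:
            key = (bin_start, comp)
            if key in seen:
                continue
            seen.add(key)
            groups.append(
                GroupObservation(
                    "truth", bin_start, frozenset(ledger.ids[i] for i in comp)
                )
            )
    return groups


def true_association_matrix(
    ledger: TrueContactLedger,
    bin_width: float = 600.0,
    period_width: float = 3600.0,
    transitive: bool = True,
) -> AssociationMatrix:
    """Score the ground-truth contact data exactly like observed data.

    Per-step contact groups (see :func:`true_groups`) are binned, aggregated
    into sampling periods and scored with the simple ratio index.
    """
    if ledger.n_steps == 0:
        raise ValidationError("empty contact ledger")
    groups = true_groups(ledger, bin_width, transitive)
    periods = collapse_to_periods(groups, period_width, bin_width)
    counts = dyad_counts(periods, individuals=ledger.ids)
    return simple_ratio_index(counts, provenance={"source": "true-contacts"})


def write_truth_contacts(ledger: TrueContactLedger, path: str | Path) -> None:
    """Export the ledger as CSV: time, individual_a, individual_b."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "individual_a", "individual_b"])
        for k, pairs in enumerate(ledger.pairs_per_step):
            t = format_time(ledger.t0 + k * ledger.step)
            for i, j in pairs:
                writer.writerow([t, ledger.ids[i], ledger.ids[j]])


def blocked_preferences(
    n: int, blocks: Sequence[Sequence[int]], weight: float = 1.0
) -> tuple[tuple[float, ...], ...]:
    """Preference matrix with uniform within-block weights, zero elsewhere.

    Individuals in no block get an all-zero row: they fall back to uniform
    site choice even on social draws, i.e. they behave as solitary.
    """
    pref = np.zeros((n, n))
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    pref[i, j] = weight
    return tuple(tuple(row) for row in pref)


def open_array_preset(
    n_individuals: int = 8,
    duration: float = 86_400.0,
    seed: int = 0,
    p_social: float = 0.0,
    preference_matrix: tuple[tuple[float, ...], ...] | None = None,
    rest_duration_mean: float = 270.0,
    receiver_radius: float = 10.0,
    site_spacing: float = 40.0,
) -> tuple[SimulationConfig, list[ReceiverSpec]]:
    """Small symmetric scenario: a 2x2 site grid, one receiver per site.

    With ``p_social=0`` individuals move independently between equivalent
    sites with short rest bouts, so group data satisfies the swap-null
    exchangeability assumptions — the calibration scenario for the
    non-randomness tests.  Pass ``preference_matrix`` and a high ``p_social``
    for the matched power scenario.
    """
    s = site_spacing
    sites = ((0.0, 0.0), (s, 0.0), (0.0, s), (s, s))
    config = SimulationConfig(
        n_individuals=n_individuals,
        duration=duration,
        site_positions=sites,
        preference_matrix=preference_matrix,
        p_social=p_social,
        rest_duration_mean=rest_duration_mean,
        site_scatter_sd=0.6,
        seed=seed,
    )
    receivers = [
        ReceiverSpec(f"R{i}", "fixed", receiver_radius, x=x, y=y)
        for i, (x, y) in enumerate(sites)
    ]
    return config, receivers


# Receiver layout mirroring one 400 m fixed receiver over a main reef, a
# second 400 m receiver over outlying sites, two 10 m receivers on gutters
# inside the first, and one 4 m animal-borne logger.
_JERVIS_SITES: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),  # main gutter, 10 m receiver A
    (35.0, 20.0),  # second gutter, 10 m receiver B; merged by >=60 m ranges
    (-80.0, 30.0),
    (150.0, -90.0),
    (250.0, 120.0),
    (900.0, 300.0),  # outlying sites, outside the main 400 m range
    (1100.0, -200.0),
)


def jervis2012_preset(
    duration_days: float = 47.0,
    n_individuals: int = 15,
    seed: int = 0,
    p_social: float = 0.85,
    rest_duration_mean: float = 7_200.0,
    site_scatter_sd: float = 0.6,
    p_det_inside: float = 1.0,
    t0: float = 1_345_852_800.0,  # 2012-08-25T00:00:00Z
) -> tuple[SimulationConfig, list[ReceiverSpec], list[IndividualSpec]]:
    """Default scenario: a mixed social/solitary population on one main reef.

    Two-thirds of the individuals belong to social blocks with strong within-
    block preferences; the rest are solitary.  Receivers: one 400 m fixed
    receiver over the main reef, a second 400 m receiver over outlying sites,
    two 10 m receivers on the two main gutters, and a 4 m animal-borne logger
    on the first individual.
    """
    n_social = (2 * n_individuals) // 3
    half = n_social // 2
    blocks = [list(range(half)), list(range(half, n_social))]
    # weak within-block background plus strong pair bonds, so small-range
    # receivers see heterogeneous dyadic structure rather than uniform blocks
    pref = np.asarray(blocked_preferences(n_individuals, blocks, weight=0.3))
    for block in blocks:
        for k in range(0, len(block) - 1, 2):
            i, j = block[k], block[k + 1]
            pref[i, j] = pref[j, i] = 4.0
    config = SimulationConfig(
        n_individuals=n_individuals,
        duration=duration_days * 86_400.0,
        site_positions=_JERVIS_SITES,
        preference_matrix=tuple(tuple(row) for row in pref),
        p_social=p_social,
        rest_duration_mean=rest_duration_mean,
        site_scatter_sd=site_scatter_sd,
        p_det_inside=p_det_inside,
        seed=seed,
        t0=t0,
    )
    host = config.individual_ids[0]
    receivers = [
        ReceiverSpec("VR2W-main", "fixed", 400.0, x=0.0, y=0.0),
        ReceiverSpec("VR2W-out", "fixed", 400.0, x=1000.0, y=0.0),
        ReceiverSpec("SUR-A", "fixed", 10.0, x=0.0, y=0.0),
        ReceiverSpec("SUR-B", "fixed", 10.0, x=35.0, y=20.0),
        ReceiverSpec("PROXI-1", "mobile", 4.0, host_individual=host),
    ]
    individuals = [
        IndividualSpec(iid, "F" if i % 2 == 0 else "M", 90.0 + 2.0 * i)
        for i, iid in enumerate(config.individual_ids)
    ]
    return config, receivers, individuals
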