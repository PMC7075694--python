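"""Event-driven simulation of dendrite number over grown length.

The model treats dendritic elaboration as a birth-death process indexed by
a length coordinate ``r`` (μm) shared by all actively growing tips: every
tip elongates at the same constant speed, and per unit of grown length each
tip branches with rate ``k_b`` (adding one tip) or terminates with rate
``k_t`` (removing one tip, leaving a terminal point at the current ``r``).
With ``n`` active tips the distance to the next event is exponential with
rate ``n (k_b + k_t)``, which the Gillespie algorithm samples exactly.

The per-tip hazard is constant, so each tip's birth-to-event distance
("segment length") is exponential with mean ``1/(k_b + k_t)`` regardless of
the population trajectory.  When ``k_t > k_b`` (subcritical) the population
goes extinct with probability 1 and the run ends; the characteristic total
dendrite length is ``1/Δk`` where ``Δk = k_t - k_b``.

A two-stage schedule switches rate constants the first time ``r`` crosses a
threshold length; by memorylessness the proposed event that would overshoot
the threshold can be discarded exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DEFAULT_MAX_EVENTS",
    "KineticStage",
    "GrowthSchedule",
    "GrowthEvent",
    "NeuronResult",
    "next_event_gap",
    "choose_event",
    "radial_distance",
    "simulate_neuron",
    "simulate_ensemble",
    "spawn_rng",
]

#: Safety cap on events per neuron; runs that hit it are flagged truncated.
DEFAULT_MAX_EVENTS = 1_000_000

_RNG_BUFFER = 4096


def spawn_rng(master_seed, *key: int) -> np.random.Generator:
    """Deterministic per-task generator.

    The splitting rule is ``SeedSequence(master_seed, spawn_key=key)``:
    stable across platforms and runs, and distinct tasks (neuron index,
    grid-cell index, replicate index, ...) get statistically independent
    streams.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass(frozen=True)
class KineticStage:
    """One (k_b, k_t) rate pair, both in μm⁻¹."""

    k_b: float
    k_t: float

    def __post_init__(self) -> None:
        if self.k_b < 0 or self.k_t < 0:
            raise ValueError(f"rates must be non-negative, got k_b={self.k_b}, k_t={self.k_t}")
        if self.k_b + self.k_t <= 0:
            raise ValueError("k_b + k_t must be positive")

    @property
    def total_rate(self) -> float:
        return self.k_b + self.k_t

    @property
    def branch_prob(self) -> float:
        """Probability that an event is a branching event."""
        return self.k_b / (self.k_b + self.k_t)

    @property
    def delta_k(self) -> float:
        """k_t - k_b; positive means subcritical (extinction certain)."""
        return self.k_t - self.k_b

    @property
    def is_supercritical(self) -> bool:
        return self.delta_k <= 0


@dataclass(frozen=True)
class GrowthSchedule:
    """Kinetic schedule for one simulated neuron.

    Parameters
    ----------
    stages
        One stage (constant rates) or two stages with a switch.
    switch_length
        Length r (μm) at which stage 2 replaces stage 1; required iff two
        stages are given.
    n0
        Initial number of dendritic tips.
    max_events
        Hard cap on events.  Defaults to :data:`DEFAULT_MAX_EVENTS`.  A
        schedule whose final stage is supercritical (k_t <= k_b) never goes
        extinct on its own and is only accepted with an explicit cap.
    """

    stages: tuple[KineticStage, ...]
    switch_length: float | None = None
    n0: int = 30
    max_events: int | None = None

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        if len(stages) not in (1, 2):
            raise ValueError("schedule needs exactly one or two stages")
        if len(stages) == 2:
            if self.switch_length is None or self.switch_length <= 0:
                raise ValueError("two-stage schedule requires switch_length > 0")
        elif self.switch_length is not None:
            raise ValueError("switch_length given for a one-stage schedule")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if stages[-1].is_supercritical and self.max_events is None:
            raise ValueError(
                "final stage has k_t <= k_b (no guaranteed extinction); "
                "pass max_events explicitly to allow a capped run"
            )
        if self.max_events is not None and self.max_events < self.n0:
            raise ValueError("max_events must be >= n0")

    @classmethod
    def one_stage(cls, k_b: float, k_t: float, n0: int = 30,
                  max_events: int | None = None) -> "GrowthSchedule":
        return cls(stages=(KineticStage(k_b, k_t),), n0=n0, max_events=max_events)

    @classmethod
    def two_stage(cls, stage1: KineticStage, stage2: KineticStage,
                  switch_length: float, n0: int = 30,
                  max_events: int | None = None) -> "GrowthSchedule":
        return cls(stages=(stage1, stage2), switch_length=switch_length,
                   n0=n0, max_events=max_events)

    @property
    def effective_max_events(self) -> int:
        return DEFAULT_MAX_EVENTS if self.max_events is None else self.max_events

    def to_dict(self) -> dict:
        d: dict = {
            "stages": [{"k_b": s.k_b, "k_t": s.k_t} for s in self.stages],
            "n0": self.n0,
        }
        if self.switch_length is not None:
            d["switch_length_um"] = self.switch_length
        if self.max_events is not None:
            d["max_events"] = self.max_events
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthSchedule":
        if "stages" in d:
            stages = tuple(KineticStage(s["k_b"], s["k_t"]) for s in d["stages"])
        else:
            stages = (KineticStage(d["k_b"], d["k_t"]),)
        return cls(stages=stages,
                   switch_length=d.get("switch_length_um"),
                   n0=int(d.get("n0", 30)),
                   max_events=d.get("max_events"))


class GrowthEvent(NamedTuple):
    r: float
    kind: str  # "branch" | "terminate"
    n_after: int


@dataclass
class NeuronResult:
    """One simulated neuron.

    ``terminal_lengths`` holds the grown-length coordinate r of every
    termination event; radial distances are ``sqrt(r)`` (Brownian mapping),
    see :func:`radial_distance`.  ``segment_lengths`` holds the
    birth-to-event distance of every tip that branched or terminated.
    Event logs are kept as parallel arrays; :attr:`events` materialises
    :class:`GrowthEvent` tuples on demand.
    """

    terminal_lengths: np.ndarray
    segment_lengths: np.ndarray
    schedule: GrowthSchedule
    seed: object
    truncated: bool
    n_branches: int
    total_length: float
    event_r: np.ndarray | None = field(default=None, repr=False)
    event_kind: np.ndarray | None = field(default=None, repr=False)  # +1 branch, -1 terminate
    event_n_after: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_terminations(self) -> int:
        return len(self.terminal_lengths)

    @property
    def events_recorded(self) -> bool:
        return self.event_r is not None

    @property
    def events(self) -> list[GrowthEvent]:
        if self.event_r is None:
            raise ValueError("event log was not recorded (record_events=False)")
        kinds = np.where(self.event_kind > 0, "branch", "terminate")
        return [GrowthEvent(float(r), str(k), int(n))
                for r, k, n in zip(self.event_r, kinds, self.event_n_after)]

    @property
    def terminal_distances(self) -> np.ndarray:
        """Radial distances sqrt(r) of all termination points (μm)."""
        return radial_distance(self.terminal_lengths)


def next_event_gap(n: int, stage: KineticStage, x1: float) -> float:
    """Length grown until the next branch/terminate event.

    Δr = -log(x1) / (n (k_b + k_t)) with x1 a uniform draw in (0, 1].
    """
    if n < 1:
        raise ValueError("no active dendrite: n must be >= 1")
    if not 0.0 < x1 <= 1.0:
        raise ValueError("x1 must lie in (0, 1]")
    return -math.log(x1) / (n * stage.total_rate)


def choose_event(stage: KineticStage, x2: float) -> str:
    """'branch' iff x2 < k_b/(k_b + k_t), else 'terminate'; x2 in [0, 1)."""
    return "branch" if x2 < stage.branch_prob else "terminate"


def radial_distance(r):
    """Radial distance R = sqrt(r) of a terminal grown length r.

    Brownian mapping: a tip wanders diffusively while it elongates, so its
    straight-line distance from the origin scales as the square root of the
    path length (unit diffusion scale of 1 μm implied).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise ValueError("grown length must be non-negative")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def simulate_neuron(schedule: GrowthSchedule, seed=None, *,
                    rng: np.random.Generator | None = None,
                    record_events: bool = True) -> NeuronResult:
    """Gillespie simulation of one neuron under ``schedule``.

    Starts with ``n0`` tips at r = 0 and repeatedly draws the event gap and
    event kind under the stage active at the current r; a random active tip
    (uniform, same RNG stream) carries each event so per-tip segment
    statistics can be reported.  Stops at extinction (n = 0) or at the
    event cap (flagged ``truncated``).  Same seed, same schedule ⇒
    bit-identical result.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    stages = schedule.stages
    n0 = schedule.n0
    max_events = schedule.effective_max_events

    k_b, k_t = stages[0].k_b, stages[0].k_t
    ktot = k_b + k_t
    p_branch = k_b / ktot
    switch = schedule.switch_length if len(stages) == 2 else math.inf
    in_stage1 = len(stages) == 2

    births = [0.0] * n0
    n = n0
    r = 0.0
    total_length = 0.0
    n_events = 0
    truncated = False
    terminals: list[float] = []
    segments: list[float] = []
    ev_r: list[float] = []
    ev_kind: list[int] = []
    ev_n: list[int] = []

    log = math.log
    buf = rng.random(_RNG_BUFFER).tolist()
    bi = 0

    while n > 0:
        if n_events >= max_events:
            truncated = True
            break
        if bi + 3 > _RNG_BUFFER:
            buf = rng.random(_RNG_BUFFER).tolist()
            bi = 0
        x1 = 1.0 - buf[bi]  # (0, 1]: guards log(0)
        dr = -log(x1) / (n * ktot)
        if in_stage1 and r + dr >= switch:
            # discard the overshooting event; exact by memorylessness
            bi += 1
            total_length += n * (switch - r)
            r = switch
            k_b, k_t = stages[1].k_b, stages[1].k_t
            ktot = k_b + k_t
            p_branch = k_b / ktot
            in_stage1 = False
            continue
        x2 = buf[bi + 1]
        u_tip = buf[bi + 2]
        bi += 3
        total_length += n * dr
        r += dr
        idx = int(u_tip * n)
        segments.append(r - births[idx])
        if x2 < p_branch:
            births[idx] = r
            births.append(r)
            n += 1
            kind = 1
        else:
            births[idx] = births[-1]
            births.pop()
            n -= 1
            kind = -1
            terminals.append(r)
        n_events += 1
        if record_events:
            ev_r.append(r)
            ev_kind.append(kind)
            ev_n.append(n)

    n_branches = n_events - len(terminals)
    return NeuronResult(
        terminal_lengths=np.asarray(terminals, dtype=float),
        segment_lengths=np.asarray(segments, dtype=float),
        schedule=schedule,
        seed=seed,
        truncated=truncated,
        n_branches=n_branches,
        total_length=total_length,
        event_r=np.asarray(ev_r) if record_events else None,
        event_kind=np.asarray(ev_kind, dtype=np.int8) if record_events else None,
        event_n_after=np.asarray(ev_n, dtype=np.int64) if record_events else None,
    )


def simulate_ensemble(schedule: GrowthSchedule, n_neurons: int, master_seed,
                      *, record_events: bool = False) -> list[NeuronResult]:
    """Simulate ``n_neurons`` independent neurons.

    Neuron ``i`` uses the generator ``spawn_rng(master_seed, i)``; results
    are reproducible and independent of execution order.  Event logs are
    off by default (memory); counts, terminals and segments are always kept.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    out = []
    for i in range(n_neurons):
        rng = spawn_rng(master_seed, i)
        res = simulate_neuron(schedule, seed=(master_seed, i), rng=rng,
                              record_events=record_events)
        out.append(res)
    return out
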