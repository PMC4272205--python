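"""Synthetic populations and PIT-tag detection streams.

This module generates data with the statistical structure that the rest of
the pipeline assumes: a captive zebra-finch-style population of families
(two parents plus a brood of chicks, half of each brood assigned to a
developmental corticosterone (CORT) treatment and half to a control) housed
in free-flying rooms, each room equipped with RFID-antenna feeders that log
timestamped PIT-tag reads as birds visit.

Foraging happens in discrete gathering events (flocks at a feeder).  Each
event recruits room members independently, with multiplicative biases that
create the social structure the analysis is meant to detect:

* ``kin_bias``   — a bird is more likely to join once a family member is in;
* ``pair_bias``  — a mated adult is more likely to join once its mate is in;
* ``cort_parent_effect``        — a CORT chick's probability of joining an
  event its parents have joined is multiplied by this factor (< 1 weakens
  the chick--parent tie);
* ``cort_gregariousness_effect`` — a CORT chick's baseline joining
  probability is multiplied by this factor (> 1 makes it join more flocks).

Ground-truth events are returned alongside the read stream so that event
detection and every downstream statistic can be scored against a known
answer.  All randomness flows from a single seed; the event skeleton
(times, durations) and the membership draws use separate child generators
so that changing a membership parameter leaves the skeleton untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400.0

__all__ = [
    "SimConfig",
    "BirdRecord",
    "TrueEvent",
    "simulate_population",
    "simulate_stream",
    "true_events_frame",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study design.

    Defaults reproduce the design of the emulated experiment: 13 families
    (two parents each) split 7 + 6 across two rooms, 37 chicks in total of
    which 20 are CORT-treated and 17 controls (split within each brood),
    two feeders per room, and 35 observation days.
    """

    n_families: int = 13
    room_split: tuple[int, ...] = (7, 6)
    brood_sizes: tuple[int, ...] | None = None  # default: 11 broods of 3, 2 of 2
    n_cort: int = 20
    n_control: int = 17
    n_days: int = 35
    feeders_per_room: int = 2
    events_per_feeder_day: float = 20.0
    event_duration_median: float = 60.0   # seconds; lognormal median
    event_duration_sigma: float = 0.5     # lognormal shape on log-seconds
    reads_per_bird_per_event_mean: float = 4.0  # geometric, support >= 1
    p_join_base: float = 0.12
    kin_bias: float = 3.0
    pair_bias: float = 4.0
    cort_parent_effect: float = 0.5
    cort_gregariousness_effect: float = 1.5
    background_noise_rate: float = 0.0    # stray reads per feeder-day, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.brood_sizes is None:
            sizes = self._default_brood_sizes()
            object.__setattr__(self, "brood_sizes", sizes)
        if len(self.brood_sizes) != self.n_families:
            raise ConfigurationError(
                f"{len(self.brood_sizes)} brood sizes for {self.n_families} families"
            )
        if any(s < 2 for s in self.brood_sizes):
            raise ConfigurationError("every brood needs >= 2 chicks for a within-brood split")
        if sum(self.room_split) != self.n_families:
            raise ConfigurationError("room_split must partition the families")
        if self.n_cort + self.n_control != sum(self.brood_sizes):
            raise ConfigurationError(
                "treatment totals must sum to the total number of chicks "
                f"({self.n_cort}+{self.n_control} != {sum(self.brood_sizes)})"
            )
        lo = sum(s // 2 for s in self.brood_sizes)
        hi = sum((s + 1) // 2 for s in self.brood_sizes)
        if not lo <= self.n_cort <= hi:
            raise ConfigurationError(
                f"n_cort={self.n_cort} unreachable with near-equal within-brood splits "
                f"(achievable range [{lo}, {hi}])"
            )
        if not 0.0 <= self.p_join_base <= 1.0:
            raise ConfigurationError("p_join_base must be a probability")
        for name in ("kin_bias", "pair_bias", "cort_parent_effect",
                     "cort_gregariousness_effect"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.reads_per_bird_per_event_mean < 1:
            raise ConfigurationError("reads_per_bird_per_event_mean must be >= 1")

    def _default_brood_sizes(self) -> tuple[int, ...]:
        n_chicks = self.n_cort + self.n_control
        base, extra = divmod(n_chicks, self.n_families)
        sizes = [base + 1] * extra + [base] * (self.n_families - extra)
        return tuple(sizes)


@dataclass(frozen=True)
class BirdRecord:
    """One individual: a PIT-tagged parent or chick."""

    tag: str
    family_id: str
    room_id: str
    role: str            # "parent" | "chick"
    sex: str             # "M" | "F"
    treatment: str       # "CORT" | "control" | "NA" (parents)
    mate_tag: str = ""   # parents only; symmetric


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth gathering event (the answer key for event detection)."""

    event_id: int
    day: int             # 1-based study day
    feeder_id: str
    room_id: str
    t_start: float       # seconds since study start
    t_end: float
    members: frozenset[str] = field(default_factory=frozenset)


def _room_ids(n_rooms: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n_rooms)]


def simulate_population(config: SimConfig) -> list[BirdRecord]:
    """Build the roster: parents with symmetric mate links, chicks with a
    within-brood treatment split as equal as parity allows.

    Brood parities that cannot all be split evenly are rounded up to CORT in
    a random subset of odd-sized broods, chosen so the configured totals are
    met exactly.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rooms = _room_ids(len(config.room_split))
    fam_rooms: list[str] = []
    for room, k in zip(rooms, config.room_split):
        fam_rooms.extend([room] * k)

    sizes = np.asarray(config.brood_sizes)
    cort_per_brood = sizes // 2
    deficit = config.n_cort - int(cort_per_brood.sum())
    odd = np.flatnonzero(sizes % 2 == 1)
    if deficit < 0 or deficit > odd.size:
        raise ConfigurationError("cannot reach treatment totals with near-equal splits")
    round_up = rng.choice(odd, size=deficit, replace=False) if deficit else np.array([], int)
    cort_per_brood[round_up] += 1

    roster: list[BirdRecord] = []
    for f in range(config.n_families):
        fam = f"F{f + 1:02d}"
        room = fam_rooms[f]
        tag_m, tag_f = f"P{f + 1:02d}M", f"P{f + 1:02d}F"
        roster.append(BirdRecord(tag_m, fam, room, "parent", "M", "NA", tag_f))
        roster.append(BirdRecord(tag_f, fam, room, "parent", "F", "NA", tag_m))
        n_chicks = int(sizes[f])
        treatments = ["CORT"] * int(cort_per_brood[f]) + \
                     ["control"] * (n_chicks - int(cort_per_brood[f]))
        rng.shuffle(treatments)
        for c in range(n_chicks):
            sex = "M" if rng.random() < 0.5 else "F"
            roster.append(BirdRecord(f"C{f + 1:02d}{chr(97 + c)}", fam, room,
                                     "chick", sex, treatments[c]))
    return roster


def _event_skeleton(config: SimConfig, rooms: Sequence[str],
                    rng: np.random.Generator) -> list[tuple[int, str, str, float, float]]:
    """Place non-overlapping event windows per feeder-day.

    Returns (day, room, feeder, t_start, t_end) tuples in stream order.
    Windows at one feeder never overlap; the two feeders of a room may.
    """
    skeleton: list[tuple[int, str, str, float, float]] = []
    for day in range(1, config.n_days + 1):
        day0 = (day - 1) * SECONDS_PER_DAY
        for room in rooms:
            for fi in range(config.feeders_per_room):
                feeder = f"{room}F{fi + 1}"
                n_ev = rng.poisson(config.events_per_feeder_day)
                if n_ev == 0:
                    continue
                durs = rng.lognormal(np.log(config.event_duration_median),
                                     config.event_duration_sigma, n_ev)
                starts = np.sort(rng.uniform(0.0, SECONDS_PER_DAY, n_ev))
                prev_end = -np.inf
                for s, d in zip(starts, durs):
                    s = max(s, prev_end + 1.0)  # push past the previous window
                    e = s + d
                    if e > SECONDS_PER_DAY:     # rare: falls off the day
                        continue
                    skeleton.append((day, room, feeder, day0 + s, day0 + e))
                    prev_end = e
    skeleton.sort(key=lambda t: (t[0], t[3], t[2]))
    return skeleton


def simulate_stream(
    roster: Sequence[BirdRecord], config: SimConfig
) -> tuple[pd.DataFrame, list[TrueEvent]]:
    """Simulate the detection stream and its ground-truth events.

    For every feeder-day a Poisson number of events is placed (non-overlapping
    per feeder).  Room members are recruited sequentially — parents first,
    then chicks, each in random order — so that kin, pair and parent-join
    status is well defined when a bird's joining probability is computed.
    Joining probabilities are ``p_join_base`` times the applicable bias
    multipliers, clipped to [0, 1].  Each joining bird emits >= 1 reads at
    uniform times inside the window.

    Returns a detection table with columns ``timestamp, tag, feeder_id``
    (sorted by time) and the list of :class:`TrueEvent`.
    """
    config = config if isinstance(config, SimConfig) else SimConfig(**config)
    ss = np.random.SeedSequence([config.seed, 1])
    rng_skel, rng_member, rng_reads_root = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    rooms = _room_ids(len(config.room_split))
    by_room: dict[str, list[BirdRecord]] = {r: [] for r in rooms}
    by_tag = {b.tag: b for b in roster}
    for b in roster:
        by_room[b.room_id].append(b)

    skeleton = _event_skeleton(config, rooms, rng_skel)

    events: list[TrueEvent] = []
    rows_t: list[float] = []
    rows_tag: list[str] = []
    rows_feeder: list[str] = []
    for eid, (day, room, feeder, t0, t1) in enumerate(skeleton):
        birds = by_room[room]
        parents = [b for b in birds if b.role == "parent"]
        chicks = [b for b in birds if b.role == "chick"]
        rng_member.shuffle(parents)
        rng_member.shuffle(chicks)
        joined: set[str] = set()
        joined_families: set[str] = set()
        for b in parents + chicks:
            p = config.p_join_base
            if b.family_id in joined_families:
                p *= config.kin_bias
            if b.mate_tag and b.mate_tag in joined:
                p *= config.pair_bias
            if b.treatment == "CORT":
                p *= config.cort_gregariousness_effect
                par = (f"P{b.family_id[1:]}M", f"P{b.family_id[1:]}F")
                if joined & set(par):
                    p *= config.cort_parent_effect
            u = rng_member.random()  # one draw per bird per event, always consumed
            if u < min(p, 1.0):
                joined.add(b.tag)
                joined_families.add(b.family_id)
        if not joined:
            continue
        # reads come from a per-event generator keyed by event id so that the
        # read stream of one event is independent of membership history
        rng_reads = np.random.default_rng(np.random.SeedSequence([config.seed, 2, eid]))
        members = frozenset(joined)
        for tag in sorted(members):
            # numpy's geometric has support >= 1 and mean 1/p
            n_reads = int(rng_reads.geometric(1.0 / config.reads_per_bird_per_event_mean))
            times = rng_reads.uniform(t0, t1, n_reads)
            rows_t.extend(times.tolist())
            rows_tag.extend([tag] * n_reads)
            rows_feeder.extend([feeder] * n_reads)
        events.append(TrueEvent(len(events), day, feeder, room, t0, t1, members))

    if config.background_noise_rate > 0 and roster:
        n_noise = rng_member.poisson(
            config.background_noise_rate * config.n_days
            * len(rooms) * config.feeders_per_room
        )
        tags_all = {r: [b.tag for b in by_room[r]] for r in rooms}
        for _ in range(n_noise):
            room = rooms[rng_member.integers(len(rooms))]
            feeder = f"{room}F{rng_member.integers(config.feeders_per_room) + 1}"
            rows_t.append(float(rng_member.uniform(0, config.n_days * SECONDS_PER_DAY)))
            rows_tag.append(tags_all[room][rng_member.integers(len(tags_all[room]))])
            rows_feeder.append(feeder)

    detections = pd.DataFrame(
        {"timestamp": rows_t, "tag": rows_tag, "feeder_id": rows_feeder}
    ).sort_values("timestamp", kind="mergesort", ignore_index=True)
    if detections.empty:
        import warnings

        warnings.warn("simulated stream is empty (no events drew any members)",
                      stacklevel=2)
    # sanity: no event mixes rooms
    for ev in events:
        assert len({by_tag[t].room_id for t in ev.members}) == 1
    return detections, events


def true_events_frame(events: Sequence[TrueEvent]) -> pd.DataFrame:
    """Tabulate ground-truth events (members ';'-separated, sorted)."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "day": [e.day for e in events],
            "feeder_id": [e.feeder_id for e in events],
            "t_start": [e.t_start for e in events],
            "t_end": [e.t_end for e in events],
            "members": [";".join(sorted(e.members)) for e in events],
        }
    )
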