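"""Gathering-event detection from bursty detection streams.

RFID feeder logs are strongly non-uniform in time: reads arrive in bursts
while a foraging flock occupies the feeder, separated by long silences.
Events (flocks) are recovered by fitting a one-dimensional Gaussian mixture
model to read timestamps, selecting the number of components by BIC, and
hard-assigning each read to its maximum-responsibility component.  This
avoids any fixed time-window threshold for defining a flock.

The stream is first partitioned by feeder and calendar day, and within a
partition coarsely pre-segmented at silences longer than ``gap_threshold``
seconds.  The pre-segmentation only bounds the mixture-fitting problem
size; it is set far above within-event read spacing so it cannot split a
real event under realistic visit rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import SECONDS_PER_DAY, BirdRecord

__all__ = [
    "GMMFit",
    "GatheringEvent",
    "GroupByIndividual",
    "fit_temporal_gmm",
    "detect_events",
    "build_gbi",
    "visits_per_event",
]

_VAR_FLOOR = 1e-6  # s^2; survives duplicate timestamps


@dataclass(frozen=True)
class GMMFit:
    """Result of a 1-D Gaussian mixture fit: parameters sorted by mean."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    labels: np.ndarray      # hard assignment per read, 0..k-1
    k: int
    log_likelihood: float


@dataclass(frozen=True)
class GatheringEvent:
    """An inferred foraging flock at one feeder."""

    event_id: int
    feeder_id: str
    day: int
    t_start: float
    t_end: float
    members: frozenset[str]
    reads_per_member: Mapping[str, int] = field(default_factory=dict)
    room_id: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an event must have at least one member")
        if self.t_start > self.t_end:
            raise ValueError("t_start must not exceed t_end")


@dataclass
class GroupByIndividual:
    """Binary events x individuals membership matrix with index metadata."""

    matrix: np.ndarray                 # (n_events, n_individuals), 0/1
    events: list[GatheringEvent]
    tags: list[str]
    rooms: list[str]                   # room label per individual
    unobserved: list[str] = field(default_factory=list)

    @property
    def days(self) -> np.ndarray:
        return np.asarray([e.day for e in self.events])

    @property
    def event_rooms(self) -> np.ndarray:
        return np.asarray([e.room_id for e in self.events])


# ---------------------------------------------------------------------------
# 1-D EM

def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on the time axis."""
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        tot = d2.sum()
        if tot <= 0:
            centers.append(x[rng.integers(x.size)])
            continue
        centers.append(x[rng.integers(x.size)] if tot == 0
                       else x[np.searchsorted(np.cumsum(d2 / tot), rng.random())])
    return np.sort(np.asarray(centers, dtype=float))


def _em_1d(x: np.ndarray, k: int, tol: float, max_iter: int,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = x.size
    mu = _kmeanspp_init(x, k, rng)
    var = np.full(k, max(np.var(x) / k, _VAR_FLOOR))
    w = np.full(k, 1.0 / k)
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step in log space
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        r = np.exp(logp - lse[:, None])
        # M-step
        nk = r.sum(axis=0) + 1e-300
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, _VAR_FLOOR)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return mu, var, w, ll


def _log_likelihood(x: np.ndarray, mu: np.ndarray, var: np.ndarray,
                    w: np.ndarray) -> tuple[float, np.ndarray]:
    logp = (
        np.log(w)[None, :]
        - 0.5 * np.log(2 * np.pi * var)[None, :]
        - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
    )
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    return float(lse.sum()), logp


def _hard_assign(x: np.ndarray, mu: np.ndarray, var: np.ndarray,
                 w: np.ndarray) -> np.ndarray:
    """Maximum responsibility; ties to the nearer mean, then lower index."""
    _, logp = _log_likelihood(x, mu, var, w)
    best = logp.max(axis=1, keepdims=True)
    tied = logp >= best - 1e-12
    dist = np.abs(x[:, None] - mu[None, :])
    dist_masked = np.where(tied, dist, np.inf)
    return dist_masked.argmin(axis=1)  # argmin takes lowest index on distance ties


def _merge_close(mu: np.ndarray, var: np.ndarray, w: np.ndarray,
                 c: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iteratively pool components whose means are closer than c*(sd_i+sd_j)."""
    mu, var, w = mu.copy(), var.copy(), w.copy()
    while mu.size > 1:
        sd = np.sqrt(var)
        gap = np.abs(mu[:, None] - mu[None, :])
        thresh = c * (sd[:, None] + sd[None, :])
        np.fill_diagonal(gap, np.inf)
        ratio = gap / np.maximum(thresh, 1e-300)
        i, j = np.unravel_index(ratio.argmin(), ratio.shape)
        if gap[i, j] >= thresh[i, j]:
            break
        wt = w[i] + w[j]
        m = (w[i] * mu[i] + w[j] * mu[j]) / wt
        v = (w[i] * (var[i] + (mu[i] - m) ** 2)
             + w[j] * (var[j] + (mu[j] - m) ** 2)) / wt
        keep = np.ones(mu.size, bool)
        keep[[i, j]] = False
        mu = np.append(mu[keep], m)
        var = np.append(var[keep], max(v, _VAR_FLOOR))
        w = np.append(w[keep], wt)
    order = np.argsort(mu)
    return mu[order], var[order], w[order]


def _has_spike(mu: np.ndarray, var: np.ndarray, w: np.ndarray, n: int) -> bool:
    """Detect the classic EM degeneracy: a floor-variance component carrying
    less than two reads whose mean lies inside another component's support.

    An isolated single-read burst also yields a floor-variance component,
    but its mean is far from every other component, so it is kept.
    """
    if mu.size < 2:
        return False
    sd = np.sqrt(var)
    for i in range(mu.size):
        if var[i] > 4 * _VAR_FLOOR or w[i] * n >= 2:
            continue
        others = np.delete(np.arange(mu.size), i)
        if np.any(np.abs(mu[others] - mu[i]) < 4 * sd[others]):
            return True
    return False


def fit_temporal_gmm(
    timestamps: Sequence[float],
    k_max: int = 10,
    tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 2,
    max_iter: int = 300,
    merge_c: float = 1.0,
    bic_patience: int = 2,
) -> GMMFit:
    """Fit a 1-D Gaussian mixture over read timestamps.

    For K = 1..k_max, run EM (``n_init`` k-means++-seeded restarts each),
    pick K by minimum BIC (stopping early once BIC has worsened for
    ``bic_patience`` consecutive K), then merge any components whose means
    are within ``merge_c`` times the sum of their SDs and re-assign reads.

    Components in the returned fit are sorted by mean and labels are
    re-indexed accordingly.  Deterministic given ``seed``.
    """
    x = np.asarray(timestamps, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one timestamp")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite timestamps in input")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        mu = np.array([x.mean()])
        return GMMFit(mu, np.array([_VAR_FLOOR]), np.array([1.0]),
                      np.zeros(x.size, dtype=int), 1, 0.0)

    rng = np.random.default_rng(np.random.SeedSequence([seed, x.size]))
    best: tuple[float, tuple] | None = None
    worse_streak = 0
    for k in range(1, min(k_max, n_distinct) + 1):
        best_k = None
        for _ in range(n_init):
            mu, var, w, ll = _em_1d(x, k, tol, max_iter, rng)
            if _has_spike(mu, var, w, x.size):
                continue
            if best_k is None or ll > best_k[3]:
                best_k = (mu, var, w, ll)
        if best_k is None:
            worse_streak += 1
            if worse_streak >= bic_patience and best is not None:
                break
            continue
        mu, var, w, ll = best_k
        n_params = 3 * k - 1
        bic = -2.0 * ll + n_params * math.log(x.size)
        if best is None or bic < best[0]:
            best = (bic, (mu, var, w, ll))
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= bic_patience:
                break

    mu, var, w, ll = best[1]
    mu, var, w = _merge_close(mu, var, w, merge_c)
    labels = _hard_assign(x, mu, var, w)
    # drop any emptied component and compact labels
    used = np.unique(labels)
    remap = {int(u): i for i, u in enumerate(used)}
    labels = np.asarray([remap[int(l)] for l in labels])
    mu, var, w = mu[used], var[used], w[used] / w[used].sum()
    ll_final, _ = _log_likelihood(x, mu, var, w)
    return GMMFit(mu, var, w, labels, mu.size, ll_final)


# ---------------------------------------------------------------------------
# stream -> events

def _segments(t: np.ndarray, gap_threshold: float) -> list[slice]:
    """Split a sorted time vector at silences longer than gap_threshold."""
    if t.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(t) > gap_threshold) + 1
    bounds = np.concatenate(([0], cuts, [t.size]))
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def detect_events(
    detections: pd.DataFrame,
    roster: Sequence[BirdRecord],
    k_max: int = 10,
    gap_threshold: float = 600.0,
    seed: int = 0,
    pool_room: bool = False,
    merge_c: float = 1.0,
    micro_gap: float = 60.0,
) -> list[GatheringEvent]:
    """Infer gathering events from a detection table.

    The stream is partitioned by (feeder, day) — or by (room, day) with
    ``pool_room`` — pre-segmented at gaps longer than ``gap_threshold``
    seconds, and a temporal Gaussian mixture fitted within each segment.
    Events with identical member sets are kept distinct: they are separate
    sampling occasions.
    """
    required = {"timestamp", "tag", "feeder_id"}
    missing = required - set(detections.columns)
    if missing:
        raise ValueError(f"detection table lacks columns: {sorted(missing)}")
    room_of = {b.tag: b.room_id for b in roster}
    unknown = sorted(set(detections["tag"]) - set(room_of))
    if unknown:
        raise ValueError(f"tags absent from roster: {unknown}")
    if detections.empty:
        return []

    df = detections.sort_values("timestamp", kind="mergesort")
    t = df["timestamp"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite timestamps in detection stream")
    # calendar days: cuts at multiples of the day length from study start
    day = np.floor_divide(t, SECONDS_PER_DAY).astype(int) + 1
    tags = df["tag"].to_numpy()
    feeders = df["feeder_id"].to_numpy()
    part_key = (np.asarray([room_of[g] for g in tags]) if pool_room else feeders)

    events: list[GatheringEvent] = []
    order = sorted(set(zip(part_key, day)))
    for pi, (part, d) in enumerate(order):
        sel = np.flatnonzero((part_key == part) & (day == d))
        if sel.size == 0:
            continue
        ts, tg, fd = t[sel], tags[sel], feeders[sel]
        for seg in _segments(ts, gap_threshold):
            st, stg, sfd = ts[seg], tg[seg], fd[seg]
            # a segment cannot hold more bursts than internal silences much
            # longer than within-burst read spacing allow; this bounds the
            # mixture size without defining the flocks themselves
            n_bursts = 1 + int(np.sum(np.diff(st) > micro_gap))
            k_cap = max(1, min(k_max, n_bursts))
            fit = fit_temporal_gmm(st, k_max=k_cap, seed=seed * 100_003 + pi,
                                   merge_c=merge_c)
            for comp in range(fit.k):
                m = fit.labels == comp
                counts: dict[str, int] = {}
                for g in stg[m]:
                    counts[g] = counts.get(g, 0) + 1
                members = frozenset(counts)
                rooms_here = {room_of[g] for g in members}
                events.append(
                    GatheringEvent(
                        event_id=len(events),
                        feeder_id=str(sfd[m][0]) if not pool_room else str(part),
                        day=int(d),
                        t_start=float(st[m].min()),
                        t_end=float(st[m].max()),
                        members=members,
                        reads_per_member=counts,
                        room_id=rooms_here.pop() if len(rooms_here) == 1 else None,
                    )
                )
    events.sort(key=lambda e: (e.day, e.t_start, e.feeder_id))
    return [
        GatheringEvent(i, e.feeder_id, e.day, e.t_start, e.t_end, e.members,
                       e.reads_per_member, e.room_id)
        for i, e in enumerate(events)
    ]


def build_gbi(events: Sequence[GatheringEvent],
              roster: Sequence[BirdRecord]) -> GroupByIndividual:
    """Assemble the binary group-by-individual matrix over the full roster.

    Individuals never observed keep an all-zero column and are listed in
    ``unobserved``.
    """
    if not events:
        raise ValueError("no events to tabulate")
    tags = [b.tag for b in roster]
    rooms = [b.room_id for b in roster]
    col = {g: j for j, g in enumerate(tags)}
    mat = np.zeros((len(events), len(tags)), dtype=np.int8)
    for i, ev in enumerate(events):
        for g in ev.members:
            mat[i, col[g]] = 1
    unobserved = [g for j, g in enumerate(tags) if mat[:, j].sum() == 0]
    return GroupByIndividual(mat, list(events), tags, rooms, unobserved)


def visits_per_event(events: Iterable[GatheringEvent], tag: str) -> np.ndarray:
    """Read counts of one bird across the events it attended (feeder visits
    within each foraging bout)."""
    return np.asarray(
        [ev.reads_per_member[tag] for ev in events if tag in ev.members],
        dtype=int,
    )
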