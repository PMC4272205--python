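"""Association networks and node-level metrics.

Edges are simple ratio index (SRI) weights: for a dyad (i, j),

    w_ij = x / (x + y_i + y_j)

where x is the number of gathering events containing both birds and y_i,
y_j the events containing exactly one of them.  Because a gathering event
at a feeder is a single group, two birds are never observed simultaneously
in *different* groups, the "both seen apart" denominator term of the
general association index is structurally zero, and the SRI reduces to the
Jaccard index of the two birds' event sets.  The general four-term form is
available for externally supplied sighting data via ``sri_general``.

Node metrics follow standard weighted-network definitions: unweighted
degree (number of associates), strength (sum of edge weights, proportional
to mean group size), betweenness (raw shortest-path counts; weighted paths
use the 1/w distance transform), eigenvector centrality (leading
eigenvector per connected component, max-normalised), social
differentiation (coefficient of variation of a bird's edge weights — high
means "choosy"), and the mean association strength of a chick to its two
parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .events import GatheringEvent, GroupByIndividual, build_gbi
from .simulate import BirdRecord

__all__ = [
    "AssociationMatrix",
    "sri",
    "sri_general",
    "daily_networks",
    "degree",
    "betweenness",
    "eigenvector_centrality",
    "social_differentiation",
    "parent_association",
    "node_metric_table",
    "repeatability",
]


@dataclass
class AssociationMatrix:
    """Symmetric SRI weight matrix over a fixed node order."""

    weights: np.ndarray
    tags: list[str]
    rooms: list[str]
    scope: str = "overall"          # "overall" or "day <d>"
    empty: bool = False             # True for a day with no events

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape[0] != w.shape[1] or w.shape[0] != len(self.tags):
            raise ValueError("weight matrix does not match node order")
        if not np.allclose(w, w.T):
            raise ValueError("association matrix must be symmetric")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("SRI weights must lie in [0, 1]")

    def index(self, tag: str) -> int:
        return self.tags.index(tag)

    def room_mask(self, tag: str) -> np.ndarray:
        room = self.rooms[self.index(tag)]
        return np.asarray([r == room for r in self.rooms])

    def to_graph(self, weighted: bool = True) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.tags)
        idx = np.argwhere(np.triu(self.weights, 1) > 0)
        for i, j in idx:
            w = float(self.weights[i, j])
            g.add_edge(self.tags[i], self.tags[j],
                       weight=w if weighted else 1.0, distance=1.0 / w)
        return g


def sri(gbi: GroupByIndividual) -> AssociationMatrix:
    """Simple ratio index from a group-by-individual matrix.

    Dyads with an empty event-set union get weight 0.  Cross-room dyads are
    structurally 0 because no event mixes rooms.
    """
    x = gbi.matrix.astype(np.float64)
    both = x.T @ x                       # co-membership counts
    n_events = np.diag(both).copy()
    union = n_events[:, None] + n_events[None, :] - both
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(union > 0, both / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    rooms = np.asarray(gbi.rooms)
    w *= (rooms[:, None] == rooms[None, :])
    return AssociationMatrix(w, list(gbi.tags), list(gbi.rooms))


def sri_general(x: np.ndarray, y_i: np.ndarray, y_j: np.ndarray,
                y_both: np.ndarray) -> np.ndarray:
    """Four-term simple ratio index x / (x + y_i + y_j + y_both).

    For sighting protocols where two individuals can be recorded at the
    same time in different groups.  With gathering-event data y_both == 0
    and this reduces to :func:`sri`.
    """
    denom = x + y_i + y_j + y_both
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), 0.0)


def daily_networks(
    events: Sequence[GatheringEvent],
    roster: Sequence[BirdRecord],
    n_days: int | None = None,
) -> list[AssociationMatrix]:
    """One association matrix per calendar day, on the full roster order.

    Both rooms share one matrix (cross-room weights 0).  A day without
    events yields an all-zero matrix flagged ``empty``.
    """
    if not events:
        raise ValueError("no events")
    days = np.asarray([e.day for e in events])
    last = int(days.max()) if n_days is None else int(n_days)
    tags = [b.tag for b in roster]
    rooms = [b.room_id for b in roster]
    out: list[AssociationMatrix] = []
    for d in range(1, last + 1):
        todays = [e for e in events if e.day == d]
        if not todays:
            out.append(AssociationMatrix(np.zeros((len(tags), len(tags))),
                                         tags, rooms, scope=f"day {d}", empty=True))
            continue
        a = sri(build_gbi(todays, roster))
        a.scope = f"day {d}"
        out.append(a)
    return out


def degree(a: AssociationMatrix, weighted: bool = False) -> np.ndarray:
    """Unweighted degree (count of positive edges) or strength (sum of
    weights)."""
    if weighted:
        return a.weights.sum(axis=1)
    return (a.weights > 0).sum(axis=1).astype(float)


def betweenness(a: AssociationMatrix, weighted: bool = False,
                normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness; weighted paths use distance 1/w.

    Raw (unnormalised) path counts by default, pairs counted once,
    endpoints excluded, tied geodesics credited fractionally; disconnected
    pairs contribute nothing.
    """
    g = a.to_graph(weighted=weighted)
    bc = nx.betweenness_centrality(
        g, weight="distance" if weighted else None, normalized=normalized
    )
    return np.asarray([bc[t] for t in a.tags])


def eigenvector_centrality(a: AssociationMatrix, tol: float = 1e-10,
                           max_iter: int = 10_000) -> np.ndarray:
    """Leading eigenvector of the weight matrix, per connected component.

    Power iteration on each component's submatrix; entries are non-negative
    (Perron–Frobenius) and rescaled to a maximum of 1 within the component.
    An all-zero matrix yields all-zero centrality with a warning.
    """
    w = a.weights
    n = w.shape[0]
    out = np.zeros(n)
    if not np.any(w > 0):
        warnings.warn("association matrix has no positive edges", stacklevel=2)
        return out
    g = nx.from_numpy_array(w)
    for comp in nx.connected_components(g):
        idx = np.asarray(sorted(comp))
        if idx.size == 1:
            continue
        sub = w[np.ix_(idx, idx)]
        # diagonal shift keeps the spectrum positive so the iteration does
        # not oscillate on bipartite components (e.g. stars); eigenvectors
        # are unchanged
        shift = float(sub.sum(axis=1).max())
        shifted = sub + shift * np.eye(idx.size)
        v = np.full(idx.size, 1.0 / np.sqrt(idx.size))
        for _ in range(max_iter):
            nv = shifted @ v
            norm = np.linalg.norm(nv)
            if norm == 0:
                break
            nv /= norm
            if np.max(np.abs(nv - v)) < tol:
                v = nv
                break
            v = nv
        v = np.abs(v)
        out[idx] = v / v.max()
    return out


def social_differentiation(a: AssociationMatrix, tag: str,
                           include_zeros: bool = True) -> float:
    """Coefficient of variation (population SD / mean) of one bird's edge
    weights to all other same-room individuals.

    Zero edges count by default: a bird associating with few of its room
    mates is maximally differentiated ("choosy").  A bird with no positive
    edge at all has an undefined ratio and is reported as 0.0.
    """
    i = a.index(tag)
    mask = a.room_mask(tag)
    mask[i] = False
    w = a.weights[i, mask]
    if w.size == 0:
        raise ValueError(f"{tag} is alone in its room; CV undefined")
    if not include_zeros:
        w = w[w > 0]
        if w.size == 0:
            return 0.0
    mean = w.mean()
    if mean == 0:
        return 0.0
    return float(w.std(ddof=0) / mean)


def _parents_of(roster: Sequence[BirdRecord], chick: BirdRecord) -> list[str]:
    return [b.tag for b in roster
            if b.family_id == chick.family_id and b.role == "parent"]


def parent_association(a: AssociationMatrix, roster: Sequence[BirdRecord],
                       chick_tag: str) -> float:
    """Mean SRI of a chick to its two parents (0 if parents unobserved)."""
    by_tag = {b.tag: b for b in roster}
    chick = by_tag.get(chick_tag)
    if chick is None or chick.role != "chick":
        raise ValueError(f"{chick_tag} is not a chick in the roster")
    parents = _parents_of(roster, chick)
    if len(parents) != 2:
        raise ValueError(f"{chick_tag} does not have exactly 2 parents on roster")
    i = a.index(chick_tag)
    return float(np.mean([a.weights[i, a.index(p)] for p in parents]))


_METRICS = (
    "degree", "strength", "betweenness", "betweenness_w",
    "eigenvector", "social_differentiation", "parent_association",
)


def node_metric_table(
    dailies: Sequence[AssociationMatrix],
    roster: Sequence[BirdRecord],
    metrics: Sequence[str] = _METRICS,
) -> pd.DataFrame:
    """Tidy per-bird per-day metric table (one column per metric).

    ``parent_association`` is defined for chicks only and left NaN for
    parents.  Empty days are skipped.
    """
    unknown = set(metrics) - set(_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    rows: list[dict] = []
    chick_tags = {b.tag for b in roster if b.role == "chick"}
    for d, a in enumerate(dailies, start=1):
        if a.empty:
            continue
        cols: dict[str, np.ndarray] = {}
        if "degree" in metrics:
            cols["degree"] = degree(a, weighted=False)
        if "strength" in metrics:
            cols["strength"] = degree(a, weighted=True)
        if "betweenness" in metrics:
            cols["betweenness"] = betweenness(a, weighted=False)
        if "betweenness_w" in metrics:
            cols["betweenness_w"] = betweenness(a, weighted=True)
        if "eigenvector" in metrics:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cols["eigenvector"] = eigenvector_centrality(a)
        for j, tag in enumerate(a.tags):
            row = {"tag": tag, "day": d}
            for name, vals in cols.items():
                row[name] = float(vals[j])
            if "social_differentiation" in metrics:
                row["social_differentiation"] = social_differentiation(a, tag)
            if "parent_association" in metrics:
                row["parent_association"] = (
                    parent_association(a, roster, tag) if tag in chick_tags
                    else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def repeatability(metric_table: pd.DataFrame, metric: str) -> dict[str, float]:
    """One-way ANOVA intraclass correlation of a daily metric across birds.

    R = (MS_among - MS_within) / (MS_among + (k0 - 1) MS_within) with the
    mean-adjusted group size k0 = (N - sum(n_i^2)/N) / (a - 1) for
    unbalanced designs.  Returns the raw value and the value clipped to
    [0, 1].
    """
    df = metric_table[["tag", "day", metric]].dropna()
    counts = df.groupby("tag").size()
    counts = counts[counts >= 2]
    df = df[df["tag"].isin(counts.index)]
    a = counts.size
    if a < 2 or df["day"].nunique() < 2:
        raise ValueError("repeatability needs >=2 birds with >=2 days each")
    y = df[metric].to_numpy(dtype=float)
    groups = df["tag"].to_numpy()
    grand = y.mean()
    n_tot = y.size
    ss_among = 0.0
    ss_within = 0.0
    for tag, ni in counts.items():
        yi = y[groups == tag]
        ss_among += ni * (yi.mean() - grand) ** 2
        ss_within += ((yi - yi.mean()) ** 2).sum()
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_tot - a)
    k0 = (n_tot - (counts.to_numpy() ** 2).sum() / n_tot) / (a - 1)
    denom = ms_among + (k0 - 1) * ms_within
    r = (ms_among - ms_within) / denom if denom != 0 else 0.0
    return {"icc": float(np.clip(r, 0.0, 1.0)), "icc_raw": float(r),
            "n_individuals": float(a), "k0": float(k0)}
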