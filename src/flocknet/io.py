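"""Readers and writers for the pipeline's tabular interchange formats.

All artefacts are plain CSV so that real RFID logger exports (any table
with ``timestamp,tag,feeder_id`` columns; extras ignored) drop straight in
for the simulated stream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import GatheringEvent, GroupByIndividual
from .network import AssociationMatrix
from .simulate import BirdRecord

ROSTER_COLUMNS = ["tag", "family_id", "room_id", "role", "sex", "treatment", "mate_tag"]
DETECTION_COLUMNS = ["timestamp", "tag", "feeder_id"]
EVENT_COLUMNS = ["event_id", "day", "feeder_id", "t_start", "t_end", "members"]


def write_roster(roster: Sequence[BirdRecord], path: str | Path) -> None:
    pd.DataFrame([vars(b) for b in roster])[ROSTER_COLUMNS].to_csv(path, index=False)


def read_roster(path: str | Path) -> list[BirdRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"roster file lacks columns: {sorted(missing)}")
    return [BirdRecord(**{c: row[c] for c in ROSTER_COLUMNS})
            for _, row in df.iterrows()]


def write_detections(detections: pd.DataFrame, path: str | Path) -> None:
    detections[DETECTION_COLUMNS].to_csv(path, index=False, float_format="%.3f")


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection file lacks columns: {sorted(missing)}")
    return df[DETECTION_COLUMNS]


def write_events(events: Sequence[GatheringEvent] | pd.DataFrame,
                 path: str | Path) -> None:
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = pd.DataFrame(
            {
                "event_id": [e.event_id for e in events],
                "day": [e.day for e in events],
                "feeder_id": [e.feeder_id for e in events],
                "t_start": [e.t_start for e in events],
                "t_end": [e.t_end for e in events],
                "members": [";".join(sorted(e.members)) for e in events],
            }
        )
    df[EVENT_COLUMNS].to_csv(path, index=False, float_format="%.3f")


def read_events(path: str | Path,
                roster: Sequence[BirdRecord] | None = None) -> list[GatheringEvent]:
    df = pd.read_csv(path)
    room_of = {b.tag: b.room_id for b in roster} if roster else {}
    out: list[GatheringEvent] = []
    for _, row in df.iterrows():
        members = frozenset(str(row["members"]).split(";"))
        rooms = {room_of[t] for t in members if t in room_of}
        out.append(
            GatheringEvent(
                event_id=int(row["event_id"]), feeder_id=str(row["feeder_id"]),
                day=int(row["day"]), t_start=float(row["t_start"]),
                t_end=float(row["t_end"]), members=members,
                reads_per_member={},
                room_id=rooms.pop() if len(rooms) == 1 else None,
            )
        )
    return out


def write_gbi(gbi: GroupByIndividual, out_dir: str | Path) -> None:
    """Sparse triplet CSV (event_idx, individual_idx, value) plus index files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(gbi.matrix)
    pd.DataFrame({"event_idx": rows, "individual_idx": cols,
                  "value": np.ones(rows.size, dtype=int)}).to_csv(
        out / "gbi_triplets.csv", index=False)
    pd.DataFrame({"individual_idx": range(len(gbi.tags)), "tag": gbi.tags,
                  "room_id": gbi.rooms}).to_csv(out / "gbi_individuals.csv",
                                                index=False)
    ev = pd.DataFrame(
        {"event_idx": range(len(gbi.events)),
         "event_id": [e.event_id for e in gbi.events],
         "day": [e.day for e in gbi.events],
         "feeder_id": [e.feeder_id for e in gbi.events]})
    ev.to_csv(out / "gbi_events.csv", index=False)


def write_network(a: AssociationMatrix, path: str | Path,
                  graphml: bool = False) -> None:
    """Edge-list CSV ``tag_i,tag_j,weight,scope`` (positive edges only),
    optionally with a GraphML sibling."""
    iu, ju = np.nonzero(np.triu(a.weights, 1))
    pd.DataFrame({"tag_i": [a.tags[i] for i in iu],
                  "tag_j": [a.tags[j] for j in ju],
                  "weight": a.weights[iu, ju],
                  "scope": a.scope}).to_csv(path, index=False, float_format="%.6f")
    if graphml:
        import networkx as nx

        nx.write_graphml(a.to_graph(), str(Path(path).with_suffix(".graphml")))


def read_network(path: str | Path,
                 roster: Sequence[BirdRecord]) -> AssociationMatrix:
    df = pd.read_csv(path)
    tags = [b.tag for b in roster]
    rooms = [b.room_id for b in roster]
    idx = {t: i for i, t in enumerate(tags)}
    w = np.zeros((len(tags), len(tags)))
    for _, row in df.iterrows():
        i, j = idx[row["tag_i"]], idx[row["tag_j"]]
        w[i, j] = w[j, i] = float(row["weight"])
    scope = str(df["scope"].iloc[0]) if len(df) else "overall"
    return AssociationMatrix(w, tags, rooms, scope=scope)


def write_metrics(metric_df: pd.DataFrame, path: str | Path) -> None:
    """Tidy long form ``tag,day,metric,value``."""
    long = metric_df.melt(id_vars=["tag", "day"], var_name="metric",
                          value_name="value")
    long.to_csv(path, index=False, float_format="%.6f")


def read_metrics(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path)
    return (long.pivot_table(index=["tag", "day"], columns="metric",
                             values="value", aggfunc="first")
            .reset_index().rename_axis(columns=None))
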