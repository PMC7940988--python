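"""Containers and CSV I/O for experimental scan-sample sessions.

A session is one run of a group cofeeding assay: a food resource is
introduced and the number of individuals inside a marked food zone is
censused at fixed time points ("scans"). Under the depleting assay
(peanut swing) the resource is consumed as the session progresses; the
constant-resource assay (juice pipe) holds it fixed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demography import ValidationError, SchemaError

ASSAYS = ("peanut_swing", "juice_pipe")

SESSION_COLUMNS = ("group", "year", "session", "assay", "n_at_risk", "scan", "time_s", "count")
IDENTITY_COLUMNS = ("group", "year", "session", "scan", "id")


@dataclasses.dataclass(frozen=True)
class SessionScans:
    """Ordered scan counts for one experimental session.

    ``identities``, when present, gives the set of individual ids in the
    food zone at each scan and must agree in cardinality with ``counts``.
    """

    group_id: str
    year: int
    session_id: str
    assay: str
    n_at_risk: int
    times_s: tuple[float, ...]
    counts: tuple[int, ...]
    identities: tuple[frozenset[str], ...] | None = None

    def __post_init__(self) -> None:
        tag = f"session {self.session_id!r} (group {self.group_id!r}, year {self.year})"
        if self.assay not in ASSAYS:
            raise ValidationError(f"{tag}: assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.n_at_risk < 1:
            raise ValidationError(f"{tag}: n_at_risk must be >= 1")
        if len(self.times_s) != len(self.counts) or not self.counts:
            raise ValidationError(f"{tag}: times and counts must be equal-length and nonempty")
        if any(t2 <= t1 for t1, t2 in zip(self.times_s, self.times_s[1:])):
            raise ValidationError(f"{tag}: scan times must be strictly increasing")
        for j, k in enumerate(self.counts):
            if not 0 <= k <= self.n_at_risk:
                raise ValidationError(
                    f"{tag}: scan {j + 1} count {k} outside [0, n_at_risk={self.n_at_risk}]"
                )
        if self.identities is not None:
            if len(self.identities) != len(self.counts):
                raise ValidationError(f"{tag}: one identity set per scan required")
            for j, (ids, k) in enumerate(zip(self.identities, self.counts)):
                if len(ids) != k:
                    raise ValidationError(
                        f"{tag}: scan {j + 1} has {len(ids)} identities but count {k}"
                    )

    @property
    def n_scans(self) -> int:
        return len(self.counts)

    @property
    def cell(self) -> tuple[str, int]:
        return (self.group_id, self.year)


def sessions_to_frame(sessions: Iterable[SessionScans]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for j, (t, k) in enumerate(zip(s.times_s, s.counts), start=1):
            rows.append(
                {
                    "group": s.group_id,
                    "year": s.year,
                    "session": s.session_id,
                    "assay": s.assay,
                    "n_at_risk": s.n_at_risk,
                    "scan": j,
                    "time_s": t,
                    "count": k,
                }
            )
    return pd.DataFrame(rows, columns=list(SESSION_COLUMNS))


def write_sessions(sessions: Iterable[SessionScans], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def load_sessions(path) -> list[SessionScans]:
    """Read the long-format sessions CSV and validate every session."""
    frame = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"sessions file {path}: missing required column(s) {missing}")
    return sessions_from_frame(frame)


def sessions_from_frame(frame: pd.DataFrame) -> list[SessionScans]:
    sessions = []
    for (gid, year, sid), block in frame.groupby(["group", "year", "session"], sort=True):
        block = block.sort_values("scan")
        assays = block["assay"].unique()
        n_vals = block["n_at_risk"].unique()
        if len(assays) > 1 or len(n_vals) > 1:
            raise ValidationError(
                f"session {sid!r} (group {gid!r}, year {year}): assay and n_at_risk "
                "must be constant within a session"
            )
        sessions.append(
            SessionScans(
                group_id=str(gid),
                year=int(year),
                session_id=str(sid),
                assay=str(assays[0]),
                n_at_risk=int(n_vals[0]),
                times_s=tuple(float(t) for t in block["time_s"]),
                counts=tuple(int(k) for k in block["count"]),
            )
        )
    return sessions


def identities_to_frame(sessions: Iterable[SessionScans]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        if s.identities is None:
            continue
        for j, ids in enumerate(s.identities, start=1):
            for ind_id in sorted(ids):
                rows.append(
                    {
                        "group": s.group_id,
                        "year": s.year,
                        "session": s.session_id,
                        "scan": j,
                        "id": ind_id,
                    }
                )
    return pd.DataFrame(rows, columns=list(IDENTITY_COLUMNS))


def write_identities(sessions: Iterable[SessionScans], path) -> None:
    identities_to_frame(sessions).to_csv(path, index=False)


def attach_identities(sessions: Sequence[SessionScans], frame: pd.DataFrame) -> list[SessionScans]:
    """Join a long-format identities table back onto sessions."""
    missing = [c for c in IDENTITY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"identities table: missing required column(s) {missing}")
    keyed = {
        (str(g), int(y), str(s)): block
        for (g, y, s), block in frame.groupby(["group", "year", "session"])
    }
    out = []
    for s in sessions:
        block = keyed.get((s.group_id, s.year, s.session_id))
        if block is None:
            out.append(s)
            continue
        per_scan = [frozenset() for _ in range(s.n_scans)]
        for scan_idx, sub in block.groupby("scan"):
            per_scan[int(scan_idx) - 1] = frozenset(str(i) for i in sub["id"])
        out.append(dataclasses.replace(s, identities=tuple(per_scan)))
    return out


def load_identities(sessions: Sequence[SessionScans], path) -> list[SessionScans]:
    return attach_identities(sessions, pd.read_csv(path))


def cell_index(sessions: Sequence[SessionScans]) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Sorted unique (group, year) cells and each session's cell index."""
    cells = sorted({s.cell for s in sessions})
    lookup = {c: i for i, c in enumerate(cells)}
    return cells, np.array([lookup[s.cell] for s in sessions], dtype=int)
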