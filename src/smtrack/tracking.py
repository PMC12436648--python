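"""Linking per-frame spots into single-molecule tracks.

Frame-to-frame linking is a gated, cost-minimizing one-to-one assignment
(linear assignment on squared displacement with birth/death alternatives),
followed by a gap-closing pass that joins track ends to later track starts.
Track-level filters implement the analysis rules for membrane-tethered
mRNA imaging: minimum track lengths per channel, a minimum imaged
duration, and exclusion of mRNA tracks whose paths cross.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Spot

__all__ = ["LinkParams", "Track", "link_frames", "close_gaps",
           "filter_tracks", "flag_crossings"]

_BIG = 1e12


@dataclass(frozen=True)
class LinkParams:
    """Linking and filtering parameters.

    Length thresholds follow the "shorter than N discarded" convention:
    a track of exactly N frames is kept.  ``min_duration_s`` applies to
    mRNA tracks (configurable via ``min_duration_channels``).
    """

    max_disp_px: float = 3.0
    max_gap_frames: int = 1
    min_len_mrna: int = 25
    min_len_protein: int = 4
    min_duration_s: float = 120.0
    crossing_radius_px: float = 2.6   # ~2 x PSF sigma
    min_duration_channels: tuple[str, ...] = ("mrna",)

    def __post_init__(self) -> None:
        for name in ("max_disp_px", "max_gap_frames", "min_len_mrna",
                     "min_len_protein", "min_duration_s",
                     "crossing_radius_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_len_mrna < self.min_len_protein:
            raise ValueError("min_len_mrna must be >= min_len_protein")

    @classmethod
    def steady_state(cls, **kw) -> "LinkParams":
        return cls(**{"min_len_mrna": 25, "min_len_protein": 4, **kw})

    @classmethod
    def runoff_uv(cls, **kw) -> "LinkParams":
        # runoff analysis: tracks shorter than five frames discarded
        return cls(**{"min_len_mrna": 5, "min_len_protein": 5, **kw})


@dataclass
class Track:
    """A time-ordered chain of spots for one molecule in one channel."""

    id: int
    channel: str
    spots: list[tuple[int, Spot]] = field(default_factory=list)
    status: str = "kept"
    reason: str | None = None

    @property
    def frames(self) -> np.ndarray:
        return np.array([f for f, _ in self.spots], dtype=int)

    @property
    def start(self) -> int:
        return self.spots[0][0]

    @property
    def end(self) -> int:
        return self.spots[-1][0]

    @property
    def n_frames(self) -> int:
        return len(self.spots)

    def duration_s(self, frame_interval_s: float) -> float:
        return (self.end - self.start + 1) * frame_interval_s

    def positions(self) -> dict[int, np.ndarray]:
        return {f: np.array([s.x, s.y]) for f, s in self.spots}

    def intensity(self, frame: int, default: float = 0.0) -> float:
        for f, s in self.spots:
            if f == frame:
                return s.integrated_intensity
        return default

    def discard(self, reason: str) -> None:
        self.status = f"discarded:{reason}"
        self.reason = reason

    @property
    def kept(self) -> bool:
        return self.status == "kept"


def _group_by_frame(spots) -> dict[int, list[Spot]]:
    if isinstance(spots, dict):
        return {int(k): list(v) for k, v in spots.items()}
    by_frame: dict[int, list[Spot]] = {}
    for item in spots:
        if isinstance(item, Spot):
            by_frame.setdefault(item.frame, []).append(item)
        else:  # list of per-frame lists
            for s in item:
                by_frame.setdefault(s.frame, []).append(s)
    return by_frame


def _gated_assignment(prev_xy: np.ndarray, new_xy: np.ndarray,
                      gate: float) -> list[tuple[int, int]]:
    """One-to-one assignment minimizing summed squared displacement.

    Uses the augmented cost matrix with per-item death/birth alternatives
    at ``gate**2`` so that unlikely links are dropped rather than forced.
    """
    n, m = len(prev_xy), len(new_xy)
    if n == 0 or m == 0:
        return []
    d2 = np.sum((prev_xy[:, None, :] - new_xy[None, :, :]) ** 2, axis=2)
    link = np.where(d2 <= gate**2, d2, _BIG)
    cost = np.full((n + m, n + m), _BIG)
    cost[:n, :m] = link
    cost[n:, m:] = 0.0
    for i in range(n):
        cost[i, m + i] = gate**2
    for j in range(m):
        cost[n + j, j] = gate**2
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    for r, c in zip(rows, cols):
        if r < n and c < m and link[r, c] < _BIG:
            pairs.append((int(r), int(c)))
    return pairs


def link_frames(spots, params: LinkParams,
                channel: str | None = None) -> list[Track]:
    """Link spots frame-to-frame into tracks.

    ``spots`` may be a flat list of :class:`Spot`, a list of per-frame
    lists, or a ``{frame: [Spot, ...]}`` mapping.  Deterministic: spots
    are processed in sorted (frame, y, x) order.
    """
    by_frame = _group_by_frame(spots)
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = itertools.count()
    for f in sorted(by_frame):
        new_spots = sorted(by_frame[f], key=lambda s: (s.y, s.x))
        if channel is None and new_spots:
            channel = new_spots[0].channel
        heads = [t for t in active if t.end == f - 1]
        pairs = _gated_assignment(
            np.array([[t.spots[-1][1].x, t.spots[-1][1].y] for t in heads])
            .reshape(len(heads), 2),
            np.array([[s.x, s.y] for s in new_spots]).reshape(len(new_spots), 2),
            params.max_disp_px,
        )
        linked_new = set()
        for ti, sj in pairs:
            heads[ti].spots.append((f, new_spots[sj]))
            linked_new.add(sj)
        for j, s in enumerate(new_spots):
            if j not in linked_new:
                t = Track(id=next(next_id), channel=channel or s.channel,
                          spots=[(f, s)])
                tracks.append(t)
                active.append(t)
        active = [t for t in active if t.end >= f - params.max_gap_frames - 1]
    return tracks


def close_gaps(tracks: list[Track], params: LinkParams) -> list[Track]:
    """Join track ends to later track starts across missed detections.

    A gap of ``g`` missed frames (``1 <= g <= max_gap_frames``) is
    closable when the end-to-start distance is within
    ``max_disp_px * sqrt(g + 1)`` (diffusive scaling).  Temporally
    overlapping tracks are never merged.  With ``max_gap_frames == 0``
    the input is returned unchanged.
    """
    if params.max_gap_frames == 0 or len(tracks) < 2:
        return tracks
    order = sorted(range(len(tracks)), key=lambda i: tracks[i].start)
    candidates = []  # (cost, end_idx, start_idx)
    for i, ti in enumerate(tracks):
        ex, ey = ti.spots[-1][1].x, ti.spots[-1][1].y
        for j in order:
            tj = tracks[j]
            gap = tj.start - ti.end - 1
            if gap < 1 or gap > params.max_gap_frames:
                continue
            sx, sy = tj.spots[0][1].x, tj.spots[0][1].y
            d2 = (ex - sx) ** 2 + (ey - sy) ** 2
            if d2 <= (params.max_disp_px**2) * (gap + 1):
                candidates.append((d2, i, j))
    if not candidates:
        return tracks
    # greedy lowest-cost join, each end/start used once; deterministic
    candidates.sort()
    used_end, used_start = set(), set()
    parent = list(range(len(tracks)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    joins = []
    for d2, i, j in candidates:
        if i in used_end or j in used_start or find(i) == find(j):
            continue
        used_end.add(i)
        used_start.add(j)
        parent[find(j)] = find(i)
        joins.append((i, j))
    # merge chains
    merged_into: dict[int, int] = {}
    for i, j in sorted(joins, key=lambda ij: tracks[ij[1]].start):
        root = i
        while root in merged_into:
            root = merged_into[root]
        tracks[root].spots.extend(tracks[j].spots)
        merged_into[j] = root
    return [t for k, t in enumerate(tracks) if k not in merged_into]


def filter_tracks(tracks: list[Track], params: LinkParams,
                  mode: str = "steady_state",
                  frame_interval_s: float = 2.0) -> list[Track]:
    """Apply track-length and duration filters; idempotent.

    Discarded tracks keep a machine-readable reason.  mRNA tracks shorter
    than ``min_len_mrna`` frames and protein/translation-site tracks
    shorter than ``min_len_protein`` frames are discarded; tracks in
    ``min_duration_channels`` must span at least ``min_duration_s``.
    """
    if mode not in ("steady_state", "runoff_uv"):
        raise ValueError(f"unknown mode {mode!r}")
    for t in tracks:
        if t.status.startswith("discarded"):
            continue
        min_len = (params.min_len_mrna if t.channel == "mrna"
                   else params.min_len_protein)
        if t.n_frames < min_len:
            t.discard("too_short")
        elif (t.channel in params.min_duration_channels
              and t.duration_s(frame_interval_s) < params.min_duration_s):
            t.discard("too_brief")
    return tracks


def flag_crossings(mrna_tracks: list[Track],
                   crossing_radius_px: float) -> list[Track]:
    """Discard mRNA tracks that approach another mRNA within the radius.

    The rule is symmetric: both members of a contacting pair are flagged.
    """
    n = len(mrna_tracks)
    pos = [t.positions() for t in mrna_tracks]
    crossing = set()
    for i in range(n):
        for j in range(i + 1, n):
            common = set(pos[i]) & set(pos[j])
            for f in common:
                if np.hypot(*(pos[i][f] - pos[j][f])) < crossing_radius_px:
                    crossing.add(i)
                    crossing.add(j)
                    break
    for k in crossing:
        if mrna_tracks[k].kept:
            mrna_tracks[k].discard("crossing")
    return mrna_tracks
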