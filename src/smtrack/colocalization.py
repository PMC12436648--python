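"""Joining protein / translation-site tracks to mRNA tracks.

A candidate pair is linked when the two tracks are within the spatial
association radius for at least the mode's minimum number of overlapping
frames (steady state: 4; runoff/UV: 2).  A linked mRNA is *colocalized*
when some run of consecutive within-radius frames reaches the mode's
event threshold (steady state: 5 frames, ~10 s; runoff/UV: 2 frames at
10-s intervals).  Per-cell fractions follow the cell-eligibility rules of
the corresponding assays (more than 15 mRNAs for the calibration ladder,
more than 10 translating mRNAs for the ligase-recruitment assays).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import Track

__all__ = ["LinkRules", "LinkedRecord", "CellSummary", "associate_tracks",
           "build_records", "call_colocalization", "classify_translating",
           "summarize_cell"]


@dataclass(frozen=True)
class LinkRules:
    """Spatial/temporal association rules for one imaging mode."""

    max_dist_px: float = 1.5
    min_overlap_frames_link: int = 4
    min_consec_frames_coloc: int = 5
    min_cell_mrna: int = 15
    min_cell_translating: int = 10
    eligibility: str = "mrna_count"     # or "translating_count"
    clip_s: float | None = 300.0        # "at least once in 5 min"

    def __post_init__(self) -> None:
        if self.max_dist_px <= 0:
            raise ValueError("max_dist_px must be > 0")
        if self.min_consec_frames_coloc < 1:
            raise ValueError("min_consec_frames_coloc must be >= 1")

    @classmethod
    def steady_state(cls, **kw) -> "LinkRules":
        return cls(**{"min_overlap_frames_link": 4,
                      "min_consec_frames_coloc": 5, "clip_s": 300.0, **kw})

    @classmethod
    def runoff_uv(cls, **kw) -> "LinkRules":
        return cls(**{"min_overlap_frames_link": 2,
                      "min_consec_frames_coloc": 2, "clip_s": None, **kw})


@dataclass
class LinkedRecord:
    """An mRNA track joined to protein and/or translation-site tracks."""

    mrna_track: Track
    protein_tracks: list[Track] = field(default_factory=list)
    tls_tracks: list[Track] = field(default_factory=list)
    frames: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    protein_within: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=bool))
    tls_within: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=bool))
    colocalized: bool = False
    events: list[tuple[int, int]] = field(default_factory=list)
    translating: bool = False
    cell_id: int = 0

    @property
    def protein_track(self) -> Track | None:
        return self.protein_tracks[0] if self.protein_tracks else None

    @property
    def overlap_frames(self) -> int:
        return int(np.sum(self.protein_within))

    def protein_trace(self) -> np.ndarray:
        """Summed linked-protein integrated intensity over mRNA frames."""
        out = np.zeros(len(self.frames))
        index = {int(f): k for k, f in enumerate(self.frames)}
        for pt in self.protein_tracks:
            for f, s in pt.spots:
                if f in index:
                    out[index[f]] += s.integrated_intensity
        return out

    def tls_trace(self) -> np.ndarray:
        out = np.zeros(len(self.frames))
        index = {int(f): k for k, f in enumerate(self.frames)}
        for tt in self.tls_tracks:
            for f, s in tt.spots:
                if f in index:
                    out[index[f]] += s.integrated_intensity
        return out

    def mrna_trace(self) -> np.ndarray:
        return np.array([s.integrated_intensity
                         for _, s in self.mrna_track.spots])


@dataclass
class CellSummary:
    cell_id: int
    n_mrna: int
    n_translating: int
    n_colocalized: int
    fraction_colocalized: float
    fraction_translating_coloc: float
    fraction_nontranslating_coloc: float
    eligible: bool


def _pair_stats(mrna: Track, other: Track,
                rules: LinkRules) -> tuple[int, float, np.ndarray]:
    """(within-radius frame count, mean distance, per-mRNA-frame within mask)."""
    mpos = mrna.positions()
    opos = other.positions()
    common = sorted(set(mpos) & set(opos))
    frames = mrna.frames
    within = np.zeros(len(frames), dtype=bool)
    if not common:
        return 0, np.inf, within
    dists = np.array([np.hypot(*(mpos[f] - opos[f])) for f in common])
    idx = {int(f): k for k, f in enumerate(frames)}
    for f, d in zip(common, dists):
        if d <= rules.max_dist_px:
            within[idx[int(f)]] = True
    return int(np.sum(dists <= rules.max_dist_px)), float(np.mean(dists)), \
        within


def associate_tracks(mrna_tracks: list[Track], other_tracks: list[Track],
                     rules: LinkRules,
                     records: list[LinkedRecord] | None = None,
                     channel: str = "protein") -> list[LinkedRecord]:
    """Assign each other-channel track to at most one mRNA track.

    A pair qualifies when the per-frame distance is within
    ``max_dist_px`` for at least ``min_overlap_frames_link`` overlapping
    frames; among qualifying mRNAs the nearest time-averaged distance
    wins, ties broken by the lower mRNA track id.  Discarded mRNA tracks
    are not linkable.  Returns one record per kept mRNA track (records
    may be passed in to accumulate several channels).
    """
    kept = [t for t in mrna_tracks if t.kept]
    if records is None:
        records = [LinkedRecord(mrna_track=t, frames=t.frames,
                                protein_within=np.zeros(t.n_frames, bool),
                                tls_within=np.zeros(t.n_frames, bool))
                   for t in kept]
    by_id = {r.mrna_track.id: r for r in records}
    # spatial prefilter: a candidate pair must come within the association
    # radius at some frame, so tracks whose mean positions are far apart
    # (allowing for within-track wander) can be skipped wholesale
    tree = None
    max_span = 0.0
    if kept:
        from scipy.spatial import cKDTree
        means, spans = [], []
        for t in kept:
            xy = np.array([[s.x, s.y] for _, s in t.spots])
            means.append(xy.mean(axis=0))
            spans.append(float(np.max(np.linalg.norm(xy - xy.mean(axis=0),
                                                     axis=1), initial=0.0)))
        tree = cKDTree(np.array(means))
        max_span = max(spans) if spans else 0.0
    for other in other_tracks:
        if not other.kept:
            continue
        oxy = np.array([[s.x, s.y] for _, s in other.spots])
        omean = oxy.mean(axis=0)
        ospan = float(np.max(np.linalg.norm(oxy - omean, axis=1),
                             initial=0.0))
        radius = rules.max_dist_px + max_span + ospan + 1e-9
        cand_idx = tree.query_ball_point(omean, radius) if tree else []
        best = None   # (mean_dist, mrna_id, within)
        for ci in sorted(cand_idx):
            mt = kept[ci]
            n_within, mean_d, within = _pair_stats(mt, other, rules)
            if n_within >= rules.min_overlap_frames_link:
                key = (mean_d, mt.id)
                if best is None or key < best[0]:
                    best = (key, mt.id, within)
        if best is not None:
            rec = by_id[best[1]]
            if channel == "protein":
                rec.protein_tracks.append(other)
                rec.protein_within |= best[2]
            else:
                rec.tls_tracks.append(other)
                rec.tls_within |= best[2]
    return records


def build_records(mrna_tracks: list[Track],
                  protein_tracks: list[Track] | None,
                  tls_tracks: list[Track] | None,
                  rules: LinkRules,
                  frame_interval_s: float = 2.0,
                  cell_id: int = 0) -> list[LinkedRecord]:
    """Associate both channels and call colocalization/translation status."""
    records = associate_tracks(mrna_tracks, protein_tracks or [], rules,
                               channel="protein")
    records = associate_tracks(mrna_tracks, tls_tracks or [], rules,
                               records=records, channel="tls")
    for rec in records:
        rec.cell_id = cell_id
        rec.translating = classify_translating(rec)
        rec.colocalized, rec.events = call_colocalization(
            rec, rules, frame_interval_s)
    return records


def _runs(mask: np.ndarray, frames: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive-frame True entries as (start, end) frames."""
    runs = []
    start = prev = None
    for f, m in zip(frames, mask):
        if m and start is None:
            start = prev = int(f)
        elif m and int(f) == prev + 1:
            prev = int(f)
        elif m:                      # True but non-consecutive frame
            runs.append((start, prev))
            start = prev = int(f)
        elif start is not None:
            runs.append((start, prev))
            start = prev = None
    if start is not None:
        runs.append((start, prev))
    return runs


def call_colocalization(record: LinkedRecord, rules: LinkRules,
                        frame_interval_s: float = 2.0
                        ) -> tuple[bool, list[tuple[int, int]]]:
    """True iff a run of consecutive within-radius frames meets the threshold.

    With ``rules.clip_s`` set, only frames within that time from the
    record's start count ("at least once in 5 min").
    """
    mask = record.protein_within.copy()
    frames = record.frames
    if rules.clip_s is not None and len(frames):
        mask &= (frames - frames[0]) * frame_interval_s < rules.clip_s
    events = [(a, b) for a, b in _runs(mask, frames)
              if b - a + 1 >= rules.min_consec_frames_coloc]
    return bool(events), events


def classify_translating(record: LinkedRecord) -> bool:
    """An mRNA is translating iff a translation-site track is linked to it."""
    return bool(record.tls_tracks)


def summarize_cell(records: list[LinkedRecord], rules: LinkRules,
                   cell_id: int | None = None) -> CellSummary:
    """Per-cell colocalization fractions and eligibility.

    Ineligible cells still carry fractions but ``eligible=False``.
    Eligibility: strictly more than ``min_cell_mrna`` mRNAs
    (calibration mode) or strictly more than ``min_cell_translating``
    translating mRNAs (ligase-recruitment mode).
    """
    if cell_id is None:
        cell_id = records[0].cell_id if records else 0
    n = len(records)
    trans = [r for r in records if r.translating]
    nontrans = [r for r in records if not r.translating]
    n_coloc = sum(r.colocalized for r in records)

    def frac(rs):
        return sum(r.colocalized for r in rs) / len(rs) if rs else float("nan")

    if rules.eligibility == "mrna_count":
        eligible = n > rules.min_cell_mrna
    elif rules.eligibility == "translating_count":
        eligible = len(trans) > rules.min_cell_translating
    else:
        raise ValueError(f"unknown eligibility rule {rules.eligibility!r}")
    return CellSummary(cell_id=cell_id, n_mrna=n, n_translating=len(trans),
                       n_colocalized=int(n_coloc),
                       fraction_colocalized=frac(records),
                       fraction_translating_coloc=frac(trans),
                       fraction_nontranslating_coloc=frac(nontrans),
                       eligible=eligible)
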