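"""Frame-to-frame particle association and velocity extraction.

Particles detected in consecutive frames are linked by the sum of weighted
absolute differences of their seven characteristics (the association cost,
or error matrix).  A globally optimal one-to-one matching over the
admissible entries realizes "smallest characteristic differences" while
structurally preventing double assignments when two bacteria cross;
particles left unmatched are recorded as disappearances (left the image
area or briefly lost) and appearances.  Chains of matches form tracks;
a track interrupted for at most ``max_gap`` frames is re-linked across the
gap, and tracks with fewer detections than ``min_track_len`` are discarded
as spurious.  Finally each frame-to-frame displacement is scaled from pixel
space to the metric space (pixel size x frame rate) to give one velocity
vector, and the vectors of a series are aggregated into a sample result.

Feature normalization: each characteristic is divided by its series-wide
median absolute value (floored at 1) so that position, area and angle are
commensurate before weighting.  The default weights put 1.0 on each
centroid coordinate and 0.2 on the five shape terms: over one frame at
30 fps position dominates, while shape disambiguates crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .optics import OpticalConfig
from .particles import FEATURE_COLUMNS

#: cost placed on gated (inadmissible) pairs so the assignment avoids them
_BIG = 1e12

#: mean detected bacteria per image above which tracking is unreliable
CROWDING_LIMIT = 15.0


@dataclass
class FeatureWeights:
    """Non-negative weight per particle characteristic."""

    cm_x: float = 1.0
    cm_y: float = 1.0
    perimeter: float = 0.2
    area: float = 0.2
    orientation: float = 0.2
    length: float = 0.2
    width: float = 0.2

    def as_array(self) -> np.ndarray:
        w = np.array([getattr(self, c) for c in FEATURE_COLUMNS], float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one > 0")
        return w


@dataclass
class CostMatrix:
    """Weighted feature distances between particles of two frames.

    ``entries[i, j]`` is the association cost between particle i of frame t
    and particle j of frame t+1; ``admissible[i, j]`` is False where the
    raw centroid displacement exceeds the gate.
    """

    entries: np.ndarray
    admissible: np.ndarray
    gate_px: float


@dataclass
class Track:
    """One bacterium's chain of detections; ``frames[i]`` may skip over
    closed gaps (a missing intermediate frame is a gap marker)."""

    id: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_gaps(self) -> int:
        return sum(b - a - 1 for a, b in zip(self.frames, self.frames[1:]))


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            prev = None
            for f, x, y in zip(t.frames, t.xs, t.ys):
                gap = prev is not None and f - prev > 1
                rows.append({"track_id": t.id, "frame": f, "x_px": x,
                             "y_px": y, "gap_flag": gap})
                prev = f
        return pd.DataFrame(rows, columns=["track_id", "frame", "x_px",
                                           "y_px", "gap_flag"])


@dataclass
class SampleResult:
    """Aggregated motility measurement for one frame series."""

    velocities: pd.DataFrame          # track_id, from_frame, speed_um_s
    mean_velocity: float              # um/s; NaN when no vectors
    sem: float                        # um/s; NaN when < 2 vectors
    n_vectors: int
    mean_bacteria_per_image: float
    qc_flag: str                      # "ok" | "too_crowded"

    def to_dict(self) -> dict:
        return {"mean_velocity_um_s": self.mean_velocity, "sem_um_s": self.sem,
                "n_vectors": self.n_vectors,
                "mean_bacteria_per_image": self.mean_bacteria_per_image,
                "qc_flag": self.qc_flag}


def normalize_features(table: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each characteristic by its series-wide robust magnitude.

    The scale is the median absolute value over the whole table, floored at
    1 so near-zero characteristics (e.g. orientation of axis-aligned rods)
    are not blown up.  Applying the normalization twice is a no-op.
    Returns the normalized copy and the scales used.
    """
    if table.empty:
        raise ValueError("cannot normalize an empty particle table")
    scales = table[FEATURE_COLUMNS].abs().median().clip(lower=1.0)
    out = table.copy()
    out[FEATURE_COLUMNS] = table[FEATURE_COLUMNS] / scales
    return out, scales


def cost_matrix(frame_t: pd.DataFrame, frame_t1: pd.DataFrame,
                weights: FeatureWeights | None = None,
                gate_px: float = 40.0,
                scales: pd.Series | None = None) -> CostMatrix:
    """Association costs between the particles of two consecutive frames.

    cost[i, j] = sum over the seven characteristics of
    w_c * |f_c(i) - f_c(j)|.  Pairs whose *raw* centroid displacement
    exceeds ``gate_px`` are inadmissible; when the tables hold normalized
    features, pass the ``scales`` from :func:`normalize_features` so the
    displacement is computed in pixels.
    """
    weights = weights or FeatureWeights()
    w = weights.as_array()
    a = frame_t[FEATURE_COLUMNS].to_numpy(float)
    b = frame_t1[FEATURE_COLUMNS].to_numpy(float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return CostMatrix(entries=np.zeros((a.shape[0], b.shape[0])),
                          admissible=np.zeros((a.shape[0], b.shape[0]), bool),
                          gate_px=gate_px)
    diff = np.abs(a[:, None, :] - b[None, :, :])
    entries = (diff * w).sum(axis=2)

    sx = sy = 1.0
    if scales is not None:
        sx, sy = float(scales["cm_x"]), float(scales["cm_y"])
    ddx = (a[:, None, 0] - b[None, :, 0]) * sx
    ddy = (a[:, None, 1] - b[None, :, 1]) * sy
    admissible = np.hypot(ddx, ddy) <= gate_px
    return CostMatrix(entries=entries, admissible=admissible, gate_px=gate_px)


def associate(e: CostMatrix) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimal-total-cost one-to-one matching over the admissible entries.

    Returns ``(matches, disappeared, appeared)``: matched (i, j) pairs,
    frame-t particles with no successor, and frame-t+1 particles with no
    predecessor.  Solved as an optimal linear assignment; inadmissible
    entries carry a prohibitive cost and any match forced onto one is
    dropped to the unmatched lists.
    """
    n, m = e.entries.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    cost = np.where(e.admissible, e.entries, _BIG)
    rows, cols = linear_sum_assignment(cost)
    matches = [(int(i), int(j)) for i, j in zip(rows, cols)
               if e.admissible[i, j]]
    matched_i = {i for i, _ in matches}
    matched_j = {j for _, j in matches}
    disappeared = [i for i in range(n) if i not in matched_i]
    appeared = [j for j in range(m) if j not in matched_j]
    return matches, disappeared, appeared


def build_tracks(table_norm: pd.DataFrame, n_frames: int,
                 weights: FeatureWeights | None = None,
                 gate_px: float = 40.0, max_gap: int = 1,
                 min_track_len: int = 5,
                 scales: pd.Series | None = None) -> TrackSet:
    """Chain frame-to-frame assignments into tracks with gap closing.

    ``table_norm`` is the (normalized) particle table over all frames; the
    raw pixel centroids are recovered through ``scales`` for gating and
    later velocity computation.  A track that misses up to ``max_gap``
    consecutive frames is re-linked to the cheapest admissible appeared
    particle (gate widened proportionally to the elapsed frames); tracks
    with fewer than ``min_track_len`` detections are removed.
    """
    weights = weights or FeatureWeights()
    sx = sy = 1.0
    if scales is not None:
        sx, sy = float(scales["cm_x"]), float(scales["cm_y"])

    by_frame = {f: g for f, g in table_norm.groupby("frame")}
    empty = table_norm.iloc[0:0]

    # active[i] / paused[i]: open track ending at a particle row; a paused
    # track missed `missed` consecutive frames (<= max_gap)
    class _Open:
        __slots__ = ("track", "row", "missed")

        def __init__(self, track, row):
            self.track, self.row, self.missed = track, row, 0

    def _extend(o: _Open, row: pd.Series, frame: int) -> None:
        o.track.frames.append(frame)
        o.track.xs.append(float(row["cm_x"]) * sx)
        o.track.ys.append(float(row["cm_y"]) * sy)
        o.row, o.missed = row, 0

    finished: list[Track] = []
    open_tracks: list[_Open] = []
    next_id = 0

    prev = by_frame.get(0, empty)
    for _, row in prev.iterrows():
        t = Track(id=next_id)
        next_id += 1
        o = _Open(t, row)
        _extend(o, row, 0)
        open_tracks.append(o)

    for f in range(1, n_frames):
        cur = by_frame.get(f, empty)
        active = [o for o in open_tracks if o.missed == 0]
        paused = [o for o in open_tracks if o.missed > 0]

        prev_rows = (pd.DataFrame([o.row for o in active])
                     if active else empty)
        e = cost_matrix(prev_rows, cur, weights, gate_px, scales)
        matches, disappeared, appeared = associate(e)

        for i, j in matches:
            _extend(active[i], cur.iloc[j], f)
        for i in disappeared:
            active[i].missed = 1

        # gap closing: pair appeared particles with paused tracks at
        # minimal cost, gate scaled by the elapsed frame span
        still_appeared = list(appeared)
        if paused and still_appeared:
            app_rows = cur.iloc[still_appeared]
            pau_rows = pd.DataFrame([o.row for o in paused])
            eg = cost_matrix(pau_rows, app_rows, weights, gate_px, scales)
            for pi, o in enumerate(paused):
                span = o.missed + 1
                dx = (pau_rows.iloc[pi]["cm_x"]
                      - app_rows["cm_x"].to_numpy()) * sx
                dy = (pau_rows.iloc[pi]["cm_y"]
                      - app_rows["cm_y"].to_numpy()) * sy
                eg.admissible[pi] = np.hypot(dx, dy) <= gate_px * span
            gmatches, _, gappeared = associate(eg)
            for pi, aj in gmatches:
                _extend(paused[pi], app_rows.iloc[aj],
                        f)
            still_appeared = [still_appeared[aj] for aj in gappeared]
            matched_p = {pi for pi, _ in gmatches}
            for pi, o in enumerate(paused):
                if pi not in matched_p:
                    o.missed += 1
        else:
            for o in paused:
                o.missed += 1

        # retire tracks lost for longer than max_gap
        for o in list(open_tracks):
            if o.missed > max_gap:
                finished.append(o.track)
                open_tracks.remove(o)

        for j in still_appeared:
            t = Track(id=next_id)
            next_id += 1
            o = _Open(t, cur.iloc[j])
            _extend(o, cur.iloc[j], f)
            open_tracks.append(o)

    finished.extend(o.track for o in open_tracks)
    kept = [t for t in finished if len(t) >= min_track_len]
    kept.sort(key=lambda t: (t.frames[0], t.ys[0], t.xs[0]))
    for new_id, t in enumerate(kept):
        t.id = new_id
    return TrackSet(tracks=kept)


def track_velocities(tracks: TrackSet, optics: OpticalConfig,
                     particles_per_frame: list[int] | np.ndarray | None = None
                     ) -> SampleResult:
    """Convert track displacements into swimming velocities and aggregate.

    Each consecutive detection pair contributes one velocity vector,
    speed = |delta centroid| * pixel_size * fps; a pair bridging a closed
    gap of g frames uses the straight-line distance over the elapsed time,
    i.e. fps / (g + 1).  The sample aggregate reports the mean and SEM
    (sd/sqrt(n)) over all vectors, the vector count, the mean number of
    detected bacteria per image, and a crowding QC flag (tracking becomes
    inaccurate above 15 bacteria per image).
    """
    px_um = optics.pixel_size_um
    rows = []
    for t in tracks.tracks:
        for (f0, x0, y0), (f1, x1, y1) in zip(
                zip(t.frames, t.xs, t.ys),
                zip(t.frames[1:], t.xs[1:], t.ys[1:])):
            dt_frames = f1 - f0
            dist_px = math.hypot(x1 - x0, y1 - y0)
            speed = dist_px * px_um * optics.fps / dt_frames
            rows.append({"track_id": t.id, "from_frame": f0,
                         "speed_um_s": speed})
    vel = pd.DataFrame(rows, columns=["track_id", "from_frame", "speed_um_s"])
    n = len(vel)
    mean = float(vel["speed_um_s"].mean()) if n else float("nan")
    sem = (float(vel["speed_um_s"].std(ddof=1) / math.sqrt(n))
           if n > 1 else float("nan"))
    if particles_per_frame is not None and len(particles_per_frame):
        per_image = float(np.mean(particles_per_frame))
    else:
        per_image = 0.0
    qc = "too_crowded" if per_image > CROWDING_LIMIT else "ok"
    return SampleResult(velocities=vel, mean_velocity=mean, sem=sem,
                        n_vectors=n, mean_bacteria_per_image=per_image,
                        qc_flag=qc)
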