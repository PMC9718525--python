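"""Organelle track extraction from kymographs.

A :class:`Track` is an ordered list of (frame, arc-length position) vertices
for one organelle; its per-segment signed velocity (µm/s, positive toward
increasing arc length) is the quantity all downstream trafficking statistics
are built from.  Tracks come from three sources sharing one schema: the
automated kymograph tracer, manual polyline imports, and simulator ground
truth.

The tracer works in two passes: per-frame 1-D peak detection with parabolic
sub-pixel refinement feeds a conservative prediction-gated linker whose
segments deliberately break at pauses, speed changes and crossings; a global
joining stage then reconnects segment ends to starts across occlusions and
stop/start transitions, with every link respecting a hard maximum speed
``v_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .imgproc import Kymograph

__all__ = [
    "Track",
    "TrackSet",
    "TraceParams",
    "trace_kymograph",
    "import_manual_tracks",
    "segment_velocities",
    "write_tracks",
    "read_tracks",
]


@dataclass
class Track:
    """One organelle's (frame, position) polyline plus hierarchy labels."""

    frames: np.ndarray  # int, strictly increasing
    positions_um: np.ndarray
    frame_interval_s: float
    track_id: str = "t0"
    marker: str = ""
    axon_id: str = "a0"
    mouse_id: str = "m0"
    dataset_id: str = "d0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.frames) < 2 or len(self.frames) != len(self.positions_um):
            raise ValueError(f"track {self.track_id}: needs ≥2 (frame, position) vertices")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frame indices must strictly increase")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_vertices(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.frame_interval_s

    @property
    def net_displacement_um(self) -> float:
        return float(self.positions_um[-1] - self.positions_um[0])

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval_s)


@dataclass
class TrackSet:
    """Tracks of one marker in one axon recording, plus axon geometry.

    ``orientation`` is +1 when increasing arc-length position is the
    anterograde direction, −1 for the opposite, and None until assigned.
    """

    tracks: list[Track]
    axon_length_um: float
    duration_min: float
    marker: str = ""
    axon_id: str = "a0"
    orientation: int | None = None

    def __post_init__(self) -> None:
        if self.orientation not in (None, 1, -1):
            raise ValueError("orientation must be +1, -1 or None")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


def segment_velocities(track: Track) -> pd.DataFrame:
    """Per consecutive vertex pair: midpoint time/position, signed velocity.

    Velocity is Δposition/Δtime in µm/s, positive toward increasing arc
    length; re-signing by axon orientation happens downstream.
    """
    t = track.times_s
    x = track.positions_um
    dt = np.diff(t)
    v = np.diff(x) / dt
    return pd.DataFrame({
        "t_mid_s": (t[:-1] + t[1:]) / 2,
        "x_mid_um": (x[:-1] + x[1:]) / 2,
        "v_um_s": v,
        "duration_s": dt,
    })


@dataclass
class TraceParams:
    """Tracer parameters; defaults are declared package conventions."""

    threshold: float | None = None  # detection threshold; None = automatic
    v_max_um_s: float = 6.0
    # occlusions (two puncta sharing one peak while crossing or co-pausing)
    # routinely last a few frames, so joins bridge up to this many missing
    # frames, with the acceptance radius widening per bridged frame
    max_gap_frames: int = 4
    min_length_frames: int = 5
    min_separation_px: int = 2
    # pass 1: accept a detection for a moving segment only within this many
    # pixels of the constant-velocity prediction (segments break at kinetic
    # state changes by design; pass 2 re-joins them)
    link_radius_px: float = 3.0
    # pass 2: largest forward/backward extrapolation mismatch for a join
    join_radius_px: float = 5.0
    # detection rows are Gaussian-smoothed by this many px before peak
    # finding (0 disables); the automatic threshold is computed after
    # smoothing; kept below the PSF width to preserve two-punctum
    # resolvability
    detect_smooth_px: float = 0.7


def _detect_row(row: np.ndarray, threshold: float, min_sep: int) -> np.ndarray:
    """Local maxima above threshold with 3-point parabolic refinement.

    Expects an already-smoothed row; symmetric puncta keep their center
    under smoothing, while shot-noise spikes are suppressed.
    """
    idx, _ = find_peaks(row, height=threshold, distance=min_sep)
    if len(idx) == 0:
        return np.empty(0)
    pos = idx.astype(float)
    interior = (idx > 0) & (idx < len(row) - 1)
    ii = idx[interior]
    denom = row[ii - 1] - 2 * row[ii] + row[ii + 1]
    ok = denom < 0
    delta = np.zeros(len(ii))
    delta[ok] = 0.5 * (row[ii - 1] - row[ii + 1])[ok] / denom[ok]
    pos[interior] += np.clip(delta, -0.5, 0.5)
    return pos


class _Segment:
    """A conservatively linked run of consecutive-frame detections."""

    __slots__ = ("frames", "cols")

    def __init__(self, frame: int, col: float):
        self.frames = [frame]
        self.cols = [col]

    def add(self, frame: int, col: float) -> None:
        self.frames.append(frame)
        self.cols.append(col)

    @property
    def vel(self) -> float | None:
        """Trailing velocity in px/frame (mean of up to last 3 steps)."""
        if len(self.cols) < 2:
            return None
        k = min(3, len(self.cols) - 1)
        return (self.cols[-1] - self.cols[-1 - k]) / k

    @property
    def vel0(self) -> float | None:
        """Leading velocity in px/frame (mean of up to first 3 steps)."""
        if len(self.cols) < 2:
            return None
        k = min(3, len(self.cols) - 1)
        return (self.cols[k] - self.cols[0]) / k


def _auto_threshold(data: np.ndarray) -> float:
    """Background median plus 5 robust sigmas (MAD-based)."""
    med = np.median(data)
    mad = np.median(np.abs(data - med))
    return float(med + 5 * 1.4826 * max(mad, 1e-12))


def trace_kymograph(kymo: Kymograph, params: TraceParams | None = None,
                    marker: str = "", axon_id: str = "a0",
                    mouse_id: str = "m0", dataset_id: str = "d0") -> TrackSet:
    """Automated two-pass kymograph tracer.

    Pass 1 detects local maxima per row (frame) above the threshold,
    localises them with 3-point parabolic fits, and links them frame-to-frame
    into conservative segments: a velocity-confirmed segment only accepts a
    detection within ``link_radius_px`` of its constant-velocity prediction
    (assignments solved jointly per frame), so segments deliberately break at
    pauses, speed changes and crossings.  Pass 2 joins segment ends to
    segment starts globally: a join is allowed across up to
    ``max_gap_frames`` missing frames when either endpoint's extrapolation
    lands within ``join_radius_px`` of the other (this covers both missed
    detections and stop/start transitions, where one side's velocity
    predicts the other's position), with the one minimising the mismatch
    winning ties (velocity continuity at crossings).  Every accepted link and
    join respects the ``v_max·Δt`` displacement gate, so no produced segment
    speed exceeds ``v_max``.  Tracks shorter than ``min_length_frames``
    vertices are discarded.
    """
    p = params or TraceParams()
    data = kymo.data
    if p.detect_smooth_px > 0:
        data = gaussian_filter1d(data, p.detect_smooth_px, axis=1,
                                 mode="nearest")
    thr = p.threshold if p.threshold is not None else _auto_threshold(data)
    um = kymo.col_spacing_um
    dt = kymo.frame_interval_s
    vmax_px = p.v_max_um_s * dt / um  # px per frame

    segments = _build_segments(data, p, thr, vmax_px)
    chains = _join_segments(segments, p, vmax_px)

    tracks = []
    k = 0
    for frames, cols in chains:
        frames, cols = _prune_glitches(frames, cols)
        if len(frames) < p.min_length_frames:
            continue
        tracks.append(Track(np.array(frames), np.array(cols) * um,
                            frame_interval_s=dt, track_id=f"tr{k}",
                            marker=marker, axon_id=axon_id,
                            mouse_id=mouse_id, dataset_id=dataset_id))
        k += 1
    length_um = (kymo.n_cols - 1) * um
    return TrackSet(tracks, axon_length_um=length_um,
                    duration_min=kymo.n_frames * dt / 60.0,
                    marker=marker, axon_id=axon_id)


def _prune_glitches(frames: list[int], cols: list[float],
                    glitch_px: float = 2.0) -> tuple[list[int], list[float]]:
    """Drop single-vertex zigzag outliers (contaminated localisations).

    A vertex is pruned when it deviates from both neighbours in the same
    direction by more than `glitch_px` — a one-frame excursion a real
    punctum cannot make and return from.  Stop/start corners are monotone
    and therefore never pruned.
    """
    while len(frames) >= 3:
        x = np.asarray(cols)
        d_prev = x[1:-1] - x[:-2]
        d_next = x[1:-1] - x[2:]
        bad = (np.sign(d_prev) == np.sign(d_next)) & \
              (np.abs(d_prev) > glitch_px) & (np.abs(d_next) > glitch_px)
        if not bad.any():
            break
        i = int(np.flatnonzero(bad)[0]) + 1
        frames = frames[:i] + frames[i + 1:]
        cols = cols[:i] + cols[i + 1:]
    return frames, cols


def _build_segments(data: np.ndarray, p: TraceParams, thr: float,
                    vmax_px: float) -> list[_Segment]:
    """Pass 1: conservative consecutive-frame segments."""
    BIG = 1e9
    live: list[_Segment] = []
    segments: list[_Segment] = []
    for t in range(data.shape[0]):
        dets = _detect_row(data[t], thr, p.min_separation_px)
        used: set[int] = set()
        if len(live) and len(dets):
            cost = np.full((len(live), len(dets)), BIG)
            for i, seg in enumerate(live):
                d = np.abs(dets - seg.cols[-1])
                if seg.vel is None:
                    # cold start: nearest neighbour within the speed gate,
                    # deprioritised against velocity-confirmed segments
                    c = 2.0 + 0.1 * d
                    ok = d <= vmax_px
                else:
                    pred = seg.cols[-1] + seg.vel
                    dp = np.abs(dets - pred)
                    c = dp
                    ok = (dp <= p.link_radius_px) & (d <= vmax_px)
                cost[i, ok] = c[ok]
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < BIG / 2:
                    live[i].add(t, float(dets[j]))
                    used.add(j)
        nxt = []
        for seg in live:
            (nxt if seg.frames[-1] == t else segments).append(seg)
        live = nxt
        live.extend(_Segment(t, float(dets[j]))
                    for j in range(len(dets)) if j not in used)
    segments.extend(live)
    return segments


def _join_segments(segments: list[_Segment], p: TraceParams,
                   vmax_px: float) -> list[tuple[list[int], list[float]]]:
    """Pass 2: global joining across gaps and stop/start events."""
    BIG = 1e9
    # A join A→B is plausible when either endpoint's constant-velocity
    # extrapolation lands on the other endpoint, and the implied bridging
    # speed respects v_max.  Joins are assigned globally (each segment end to
    # at most one segment start) and chained.
    order = sorted(range(len(segments)), key=lambda k: segments[k].frames[0])
    segments = [segments[k] for k in order]
    n = len(segments)
    ends = np.array([s.frames[-1] for s in segments])
    starts = np.array([s.frames[0] for s in segments])
    cost = np.full((n, n), BIG)
    for a in range(n):
        sa = segments[a]
        for b in range(n):
            if a == b:
                continue
            df = starts[b] - ends[a]
            if df < 1 or df > p.max_gap_frames + 1:
                continue
            sb = segments[b]
            dx = sb.cols[0] - sa.cols[-1]
            if abs(dx) > vmax_px * df:
                continue
            # three hypotheses: A kept moving, B was already moving, or the
            # particle paused through the gap (dx ≈ 0); the pause hypothesis
            # carries a penalty so that, at a pause-crossing, a consistent
            # constant-velocity continuation always outbids it
            mism = [abs(dx) + 2.0]
            if sa.vel is not None:
                mism.append(abs(dx - sa.vel * df))
            if sb.vel0 is not None:
                mism.append(abs(dx - sb.vel0 * df))
            if sa.vel is None and sb.vel0 is None:
                mism.append(abs(dx))
            m = min(mism)
            if m <= p.join_radius_px + 1.0 * (df - 1):
                cost[a, b] = m + 0.5 * (df - 1)
    succ = _assign_with_skip(cost, skip_cost=p.join_radius_px)
    has_pred = set(succ.values())

    chains = []
    for a in range(n):
        if a in has_pred:
            continue
        frames, cols = list(segments[a].frames), list(segments[a].cols)
        b = a
        while b in succ:
            b = succ[b]
            frames.extend(segments[b].frames)
            cols.extend(segments[b].cols)
        chains.append((frames, cols))
    return _rejoin_chains(chains, p, vmax_px)


def _assign_with_skip(cost: np.ndarray, skip_cost: float) -> dict[int, int]:
    """One-to-one assignment where every row may stay unmatched at
    `skip_cost`; a candidate pairing worse than that is never forced in to
    raise the matching count (the classic pitfall of plain Hungarian
    linking)."""
    n = cost.shape[0]
    if n == 0:
        return {}
    padded = np.hstack([cost, np.full((n, n), 1e9)])
    padded[np.arange(n), n + np.arange(n)] = skip_cost
    ri, ci = linear_sum_assignment(padded)
    return {a: b for a, b in zip(ri, ci) if b < n and cost[a, b] < 1e8}


def _rejoin_chains(chains, p: TraceParams, vmax_px: float,
                   max_rounds: int = 4):
    """Relaxed second-stage joining of whole chains.

    Longer occlusions (e.g. two organelles co-pausing under one peak) leave
    clean chains separated by more frames than the strict join pass bridges.
    A chain end is glued to a later chain start only when the pairing is
    unambiguous in both directions under the relaxed gate (twice the join
    radius, up to ``2·(max_gap+1)`` missing frames); repeated until stable.
    """
    BIG = 1e9
    max_df = 2 * (p.max_gap_frames + 1)
    # a punctum occluded by a co-pausing neighbour can vanish for tens of
    # frames while standing still; such stationary bridges are identifiable
    # (both endpoints slow, same position) and may span much longer gaps
    max_df_pause = 5 * (p.max_gap_frames + 1)
    for _ in range(max_rounds):
        n = len(chains)
        cost = np.full((n, n), BIG)
        for a in range(n):
            fa, ca = chains[a]
            va = (ca[-1] - ca[max(len(ca) - 4, 0)]) / max(min(3, len(ca) - 1), 1)
            for b in range(n):
                if a == b:
                    continue
                fb, cb = chains[b]
                df = fb[0] - fa[-1]
                if df < 1 or df > max_df_pause:
                    continue
                dx = cb[0] - ca[-1]
                if abs(dx) > vmax_px * df:
                    continue
                vb = (cb[min(3, len(cb) - 1)] - cb[0]) / max(min(3, len(cb) - 1), 1)
                m = min(abs(dx) + 2.0, abs(dx - va * df), abs(dx - vb * df))
                if df > max_df:
                    # long gaps only as stationary (co-pause) bridges
                    if not (abs(dx) <= p.join_radius_px
                            and abs(va) <= 1.0 and abs(vb) <= 1.0):
                        continue
                    m = abs(dx)
                # short gaps were already offered to the strict pass; only a
                # modestly relaxed gate is justified here, growing with the
                # number of bridged frames
                if m <= p.join_radius_px + 1.0 * min(df, max_df):
                    cost[a, b] = m + 0.2 * min(df, max_df)
        succ = _assign_with_skip(cost, skip_cost=p.join_radius_px)
        if not succ:
            break
        has_pred = set(succ.values())
        merged_chains = []
        for a in range(n):
            if a in has_pred:
                continue
            frames, cols = list(chains[a][0]), list(chains[a][1])
            b = a
            while b in succ:
                b = succ[b]
                frames.extend(chains[b][0])
                cols.extend(chains[b][1])
            merged_chains.append((frames, cols))
        if len(merged_chains) == len(chains):
            break
        chains = merged_chains
    return chains


def import_manual_tracks(path, pixel_size_um: float, frame_interval_s: float,
                         axon_length_um: float | None = None,
                         position_column: str = "position_px",
                         **track_labels) -> TrackSet:
    """Load manually drawn kymograph polylines from CSV.

    The file must have columns ``track_id``, ``frame`` and either
    ``position_px`` (converted with `pixel_size_um`) or ``position_um``.
    Frames must strictly increase within each track; violations are rejected
    with an error naming the track.
    """
    df = pd.read_csv(path)
    if position_column not in df.columns:
        if "position_um" in df.columns:
            position_column = "position_um"
        else:
            raise ValueError(f"no {position_column!r} or 'position_um' column in {path}")
    scale = 1.0 if position_column == "position_um" else pixel_size_um
    tracks = []
    max_frame = 0
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {tid!r}: frames must strictly increase")
        pos = grp[position_column].to_numpy() * scale
        if np.any(pos < 0):
            raise ValueError(f"track {tid!r}: negative positions")
        if axon_length_um is not None and np.any(pos > axon_length_um):
            raise ValueError(f"track {tid!r}: vertex outside kymograph bounds")
        tracks.append(Track(frames, pos, frame_interval_s=frame_interval_s,
                            track_id=str(tid), **track_labels))
        max_frame = max(max_frame, int(frames[-1]))
    if not tracks:
        warnings.warn(f"no tracks found in {path}")
    length = axon_length_um if axon_length_um is not None else (
        max((tr.positions_um.max() for tr in tracks), default=0.0))
    return TrackSet(tracks, axon_length_um=float(length),
                    duration_min=(max_frame + 1) * frame_interval_s / 60.0)


def benchmark_tracking(traced: TrackSet, truth: TrackSet,
                       match_tolerance_um: float = 1.0,
                       min_overlap_fraction: float = 0.5) -> dict:
    """Score traced tracks against ground truth.

    A truth track is *recalled* when some traced track overlaps at least
    `min_overlap_fraction` of its frames with mean |Δposition| ≤ the match
    tolerance.  Speed RMSE compares, for every consecutive traced vertex
    pair inside the overlap, the traced segment velocity with the truth
    displacement over the same frames — the tracer claims no position at
    frames it bridged, so bridged intervals are scored on their average
    velocity.  Returns recall, n_matched, and speed RMSE (µm/s).
    """
    def interp(tr: Track):
        f = np.arange(tr.frames[0], tr.frames[-1] + 1)
        return f, np.interp(f, tr.frames, tr.positions_um)

    dt = truth.tracks[0].frame_interval_s if len(truth) else 1.0
    matched = 0
    sq_err: list[float] = []
    for tt in truth:
        f2, x2 = interp(tt)
        best = None
        for tr in traced:
            f1, x1 = interp(tr)
            lo, hi = max(f1[0], f2[0]), min(f1[-1], f2[-1])
            if hi < lo or (hi - lo + 1) < min_overlap_fraction * len(f2):
                continue
            a = x1[lo - f1[0]: hi - f1[0] + 1]
            b = x2[lo - f2[0]: hi - f2[0] + 1]
            d = float(np.mean(np.abs(a - b)))
            if d <= match_tolerance_um and (best is None or d < best[0]):
                best = (d, tr, lo, hi)
        if best is not None:
            matched += 1
            _, tr, lo, hi = best
            sel = (tr.frames >= lo) & (tr.frames <= hi)
            vf = tr.frames[sel]
            vx = tr.positions_um[sel]
            if len(vf) >= 2:
                df = np.diff(vf)
                va = np.diff(vx) / (df * dt)
                xb = np.interp(vf, f2, x2)
                vb = np.diff(xb) / (df * dt)
                sq_err.extend((va - vb) ** 2)
    recall = matched / len(truth) if len(truth) else np.nan
    rmse = float(np.sqrt(np.mean(sq_err))) if sq_err else np.nan
    return {"recall": recall, "n_truth": len(truth), "n_traced": len(traced),
            "n_matched": matched, "speed_rmse_um_s": rmse}


def write_tracks(trackset: TrackSet, path) -> None:
    """Write tracks as flat CSV (track_id, frame, position_um)."""
    rows = []
    for tr in trackset:
        for f, x in zip(tr.frames, tr.positions_um):
            rows.append((tr.track_id, tr.marker, int(f), x))
    pd.DataFrame(rows, columns=["track_id", "marker", "frame", "position_um"]) \
        .to_csv(path, index=False, float_format="%.6f")


def read_tracks(path, frame_interval_s: float, axon_length_um: float,
                **track_labels) -> TrackSet:
    ts = import_manual_tracks(path, pixel_size_um=1.0,
                              frame_interval_s=frame_interval_s,
                              axon_length_um=axon_length_um,
                              position_column="position_um", **track_labels)
    return ts
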