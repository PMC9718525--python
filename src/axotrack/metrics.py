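"""Trafficking statistics on track sets.

Implements the standard kymograph-derived quantities: moving/stationary
classification by net displacement, anterograde orientation assignment
(plus-end comet channel when available, otherwise the faster mean direction),
per-track mean moving speed and time-weighted pause fraction, relative flux
(fraction of moving tracks whose main vector is anterograde), absolute flux
(moving organelles per µm axon per minute), the dual-marker axon inclusion
filter, and a dual-channel co-movement check.

Convention: segment velocities are signed toward increasing arc length; after
orientation assignment, velocity × orientation > 0 means anterograde.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .tracking import Track, TrackSet, segment_velocities

__all__ = [
    "FluxSummary",
    "classify_moving",
    "assign_direction",
    "summarize_tracks",
    "compute_flux",
    "filter_axons",
    "co_movement_fraction",
    "PAUSE_THRESHOLD_SWEEP",
]

#: pause-speed definitions exposed for the enrichment sweep (µm/s);
#: 0 means "speed exactly 0", the others are strict upper bounds.
PAUSE_THRESHOLD_SWEEP = (0.0, 0.2, 0.5, 1.0)

#: default net-displacement threshold separating moving from stationary (µm)
DEFAULT_MOVING_THRESHOLD_UM = 2.0

#: default pause speed threshold (µm/s): sub-quantization motion counts as 0
DEFAULT_PAUSE_THRESHOLD = 0.1


def classify_moving(track: Track,
                    min_net_displacement_um: float = DEFAULT_MOVING_THRESHOLD_UM
                    ) -> bool:
    """A track is moving iff |net displacement| ≥ the threshold."""
    return abs(track.net_displacement_um) >= min_net_displacement_um


def _mean_moving_speed_and_direction(ts: TrackSet, sign: int,
                                     min_net: float) -> tuple[float, float]:
    """Time-weighted mean |v| of moving tracks whose net displacement has
    the given sign (in raw arc-length coordinates)."""
    num = den = 0.0
    for tr in ts:
        if not classify_moving(tr, min_net):
            continue
        if np.sign(tr.net_displacement_um) != sign:
            continue
        seg = segment_velocities(tr)
        num += (seg["v_um_s"].abs() * seg["duration_s"]).sum()
        den += seg["duration_s"].sum()
    return (num / den if den > 0 else np.nan), den


def assign_direction(trackset: TrackSet,
                     comet_trackset: TrackSet | None = None,
                     min_net_displacement_um: float = DEFAULT_MOVING_THRESHOLD_UM
                     ) -> TrackSet:
    """Set the anterograde orientation of a track set.

    With a plus-end comet channel the orientation is the modal sign of comet
    net displacements (comets only grow anterogradely).  Without comets the
    direction with the larger mean moving speed is labelled anterograde —
    the convention validated against the comet marker.  Exactly tied mean
    speeds without comets leave the orientation unset with a warning.
    """
    if comet_trackset is not None:
        signs = [np.sign(tr.net_displacement_um) for tr in comet_trackset
                 if classify_moving(tr, min_net_displacement_um)]
        if not signs:
            raise ValueError("comet track set has no moving tracks")
        orientation = 1 if sum(signs) >= 0 else -1
        return replace(trackset, orientation=orientation)
    plus, _ = _mean_moving_speed_and_direction(trackset, 1, min_net_displacement_um)
    minus, _ = _mean_moving_speed_and_direction(trackset, -1, min_net_displacement_um)
    if np.isnan(plus) and np.isnan(minus):
        raise ValueError("no moving tracks; cannot assign direction")
    if np.isnan(minus) or (not np.isnan(plus) and plus > minus):
        return replace(trackset, orientation=1)
    if np.isnan(plus) or minus > plus:
        return replace(trackset, orientation=-1)
    warnings.warn("mean speeds exactly tied and no comet channel; "
                  "orientation left unset")
    return replace(trackset, orientation=None)


def summarize_tracks(trackset: TrackSet,
                     pause_threshold_um_s: float = DEFAULT_PAUSE_THRESHOLD,
                     min_net_displacement_um: float = DEFAULT_MOVING_THRESHOLD_UM,
                     include_pauses_in_speed: bool = False) -> pd.DataFrame:
    """Per-track metrics table.

    Mean moving speed is the time-weighted mean |v| over segments faster than
    the pause threshold (NaN when the track never moves); with
    ``include_pauses_in_speed`` all segments enter the mean.  Pause fraction
    is the time-weighted fraction of segments with |v| ≤ threshold.  The
    direction label comes from the sign of the net displacement re-signed by
    the set's orientation.
    """
    if trackset.orientation is None:
        raise ValueError("orientation must be assigned before summarising")
    o = trackset.orientation
    rows = []
    for tr in trackset:
        seg = segment_velocities(tr)
        speed = seg["v_um_s"].abs()
        dur = seg["duration_s"]
        pausing = speed <= pause_threshold_um_s
        pause_frac = float(dur[pausing].sum() / dur.sum())
        sel = slice(None) if include_pauses_in_speed else ~pausing
        moving_dur = dur[sel].sum()
        mean_speed = float((speed[sel] * dur[sel]).sum() / moving_dur) \
            if moving_dur > 0 else np.nan
        net = tr.net_displacement_um * o
        rows.append({
            "track_id": tr.track_id,
            "marker": tr.marker,
            "axon_id": tr.axon_id,
            "mouse_id": tr.mouse_id,
            "dataset_id": tr.dataset_id,
            "moving": classify_moving(tr, min_net_displacement_um),
            "direction": "antero" if net > 0 else ("retro" if net < 0 else "none"),
            "mean_moving_speed_um_s": mean_speed,
            "pause_fraction": pause_frac,
            "net_displacement_um": net,
            "duration_s": tr.duration_s,
        })
    return pd.DataFrame(rows)


@dataclass
class FluxSummary:
    """Relative and absolute flux of moving organelles in one axon."""

    n_moving: int
    n_antero: int
    n_retro: int
    relative_flux_antero: float  # fraction of moving tracks with antero main vector
    relative_flux_retro: float
    absolute_flux: float         # moving organelles / µm axon / minute

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_flux(trackset: TrackSet, metrics_table: pd.DataFrame) -> FluxSummary:
    """Relative flux = n_antero/n_moving; absolute flux = n_moving/(L·T).

    Undefined (NaN) when no track is moving, rather than zero.
    """
    if trackset.axon_length_um <= 0 or trackset.duration_min <= 0:
        raise ValueError("axon length and duration must be positive")
    mv = metrics_table[metrics_table["moving"]]
    n = len(mv)
    n_a = int((mv["direction"] == "antero").sum())
    n_r = int((mv["direction"] == "retro").sum())
    if n == 0:
        return FluxSummary(0, 0, 0, np.nan, np.nan, np.nan)
    return FluxSummary(
        n_moving=n, n_antero=n_a, n_retro=n_r,
        relative_flux_antero=n_a / n,
        relative_flux_retro=n_r / n,
        absolute_flux=n / (trackset.axon_length_um * trackset.duration_min),
    )


def filter_axons(tracksets_by_axon: dict[str, dict[str, TrackSet]],
                 min_moving: int = 3,
                 min_net_displacement_um: float = DEFAULT_MOVING_THRESHOLD_UM
                 ) -> list[str]:
    """Axon inclusion filter for multi-marker recordings.

    An axon is included iff every analysed marker has at least `min_moving`
    moving tracks and at least one moving track per direction (by raw
    net-displacement sign; the rule is orientation-free).
    """
    included = []
    for axon_id, per_marker in tracksets_by_axon.items():
        ok = True
        for ts in per_marker.values():
            signs = [np.sign(tr.net_displacement_um) for tr in ts
                     if classify_moving(tr, min_net_displacement_um)]
            if len(signs) < min_moving or (1 not in signs) or (-1 not in signs):
                ok = False
                break
        if ok:
            included.append(axon_id)
    return included


def _interp_positions(track: Track) -> tuple[np.ndarray, np.ndarray]:
    frames = np.arange(track.frames[0], track.frames[-1] + 1)
    return frames, np.interp(frames, track.frames, track.positions_um)


def co_movement_fraction(trackset_a: TrackSet, trackset_b: TrackSet,
                         position_tolerance_um: float = 0.5,
                         min_overlap_frames: int = 5,
                         min_matched_fraction: float = 0.8
                         ) -> tuple[float, float]:
    """Fraction of A-tracks co-moving with some B-track (and symmetric).

    Two tracks match iff over their temporal overlap (at least
    `min_overlap_frames` frames) the fraction of frames with
    |position difference| ≤ tolerance reaches `min_matched_fraction`.
    """
    def matched(ts1: TrackSet, ts2: TrackSet) -> float:
        if len(ts1) == 0:
            return np.nan
        interp2 = [_interp_positions(tr) for tr in ts2]
        hits = 0
        for tr in ts1:
            f1, x1 = _interp_positions(tr)
            for f2, x2 in interp2:
                lo, hi = max(f1[0], f2[0]), min(f1[-1], f2[-1])
                if hi - lo + 1 < min_overlap_frames:
                    continue
                a = x1[lo - f1[0]: hi - f1[0] + 1]
                b = x2[lo - f2[0]: hi - f2[0] + 1]
                if np.mean(np.abs(a - b) <= position_tolerance_um) >= min_matched_fraction:
                    hits += 1
                    break
        return hits / len(ts1)

    return matched(trackset_a, trackset_b), matched(trackset_b, trackset_a)
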