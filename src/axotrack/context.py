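"""Spatial and temporal context for speed samples.

Two analyses hang off the per-segment speed samples produced by tracking:

* **Synapse proximity.**  Synapse centers detected from a synapse-marker
  channel define 1-D masks (disks or annuli along arc length); pauses are
  compared with the count expected under spatial uniformity
  (total pauses × mask length fraction) to give an enrichment factor, and
  samples are split into synapse vs shaft for speed comparisons.

* **Calcium activity.**  A ΔF/F trace thresholded at half its maximum defines
  an active state; maximal active runs can be extended by a fixed
  post-activity window (+5 s, +30 s) before samples are labelled
  active/rest.  Stimulation epochs label samples before/during/after.

Speed samples live in one flat DataFrame (columns ``t_mid_s``, ``x_mid_um``,
``v_um_s``, ``speed`` (=|v|), ``direction``, ``location``, ``activity``,
``epoch``, plus hierarchy ids) — the sole input of the stats module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .imgproc import AxonPath, Movie
from .metrics import DEFAULT_MOVING_THRESHOLD_UM, classify_moving
from .tracking import TrackSet, segment_velocities

__all__ = [
    "SynapseMask",
    "EnrichmentResult",
    "ActivityTrace",
    "detect_synapse_centers",
    "build_synapse_mask",
    "speed_samples",
    "pause_enrichment",
    "label_location",
    "compute_dff",
    "active_state",
    "label_activity",
    "label_epoch",
    "roi_trace",
]

#: the standard radius sweep for synapse masks (µm)
RADIUS_SWEEP = ((0.0, 0.5), (0.5, 1.5), (1.5, 2.5))


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    iv = sorted((a, b) for a, b in iv if b > a)
    out: list[list[float]] = []
    for a, b in iv:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _subtract_intervals(keep, cut):
    out = []
    for a, b in keep:
        segs = [(a, b)]
        for c, d in cut:
            nxt = []
            for s, e in segs:
                if d <= s or c >= e:
                    nxt.append((s, e))
                else:
                    if s < c:
                        nxt.append((s, c))
                    if d < e:
                        nxt.append((d, e))
            segs = nxt
        out.extend(segs)
    return _merge_intervals(out)


@dataclass
class SynapseMask:
    """Union of arc-length intervals around synapse centers.

    ``inner_um = 0`` gives disks of radius ``outer_um``; ``inner_um > 0``
    gives annulus ("donut") bands: (union of outer disks) minus (union of
    inner disks), so positions inside any center's inner disk are excluded.
    """

    centers_um: np.ndarray
    inner_um: float
    outer_um: float
    axon_length_um: float
    intervals: list[tuple[float, float]] = field(init=False)
    mask_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.inner_um < self.outer_um):
            raise ValueError("need 0 ≤ inner < outer radius")
        if self.axon_length_um <= 0:
            raise ValueError("axon length must be positive")
        self.centers_um = np.asarray(self.centers_um, dtype=float)
        L = self.axon_length_um
        clip = lambda a, b: (max(a, 0.0), min(b, L))
        outer = _merge_intervals([clip(c - self.outer_um, c + self.outer_um)
                                  for c in self.centers_um])
        if self.inner_um > 0:
            inner = _merge_intervals([clip(c - self.inner_um, c + self.inner_um)
                                      for c in self.centers_um])
            self.intervals = _subtract_intervals(outer, inner)
        else:
            self.intervals = outer
        self.mask_fraction = sum(b - a for a, b in self.intervals) / L

    def contains(self, positions_um) -> np.ndarray:
        x = np.asarray(positions_um, dtype=float)
        inside = np.zeros(x.shape, dtype=bool)
        for a, b in self.intervals:
            inside |= (x >= a) & (x <= b)
        return inside


def detect_synapse_centers(profile_um_spacing: float, profile: np.ndarray,
                           prominence: float | None = None,
                           min_separation_um: float = 1.0) -> np.ndarray:
    """Synapse centers from a time-averaged synapse-channel intensity profile.

    Centers are local maxima above the prominence threshold (default: 25% of
    the profile's dynamic range), separated by at least `min_separation_um`,
    refined by 3-point parabolic fits; returned in µm from the profile start.
    A flat profile yields an empty list with a warning.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) == 0:
        raise ValueError("empty profile")
    rng = profile.max() - profile.min()
    if rng == 0:
        warnings.warn("flat synapse profile; no centers detected")
        return np.empty(0)
    if prominence is None:
        prominence = 0.25 * rng
    dist = max(int(round(min_separation_um / profile_um_spacing)), 1)
    idx, _ = find_peaks(profile, prominence=prominence, distance=dist)
    pos = idx.astype(float)
    interior = (idx > 0) & (idx < len(profile) - 1)
    ii = idx[interior]
    denom = profile[ii - 1] - 2 * profile[ii] + profile[ii + 1]
    ok = denom < 0
    delta = np.zeros(len(ii))
    delta[ok] = 0.5 * (profile[ii - 1] - profile[ii + 1])[ok] / denom[ok]
    pos[interior] += np.clip(delta, -0.5, 0.5)
    return pos * profile_um_spacing


def build_synapse_mask(centers_um, inner_um: float, outer_um: float,
                       axon_length_um: float) -> SynapseMask:
    """Convenience constructor for :class:`SynapseMask`."""
    return SynapseMask(np.asarray(centers_um, dtype=float), inner_um, outer_um,
                       axon_length_um)


def speed_samples(trackset: TrackSet) -> pd.DataFrame:
    """Flatten a track set into per-segment speed samples.

    ``v_um_s`` is re-signed by the set's orientation (positive = anterograde);
    ``speed`` is |v|.  The per-sample direction label is the track's main
    direction (sign of its net displacement after orientation), so paused
    segments inherit their track's direction.  Location/activity/epoch labels
    start as 'shaft'/'rest'/'none' and are refined by the label_* operations.
    """
    if trackset.orientation is None:
        raise ValueError("orientation must be assigned before sampling")
    o = trackset.orientation
    cols: dict[str, list] = {k: [] for k in
                             ("t_mid_s", "x_mid_um", "v_um_s", "duration_s",
                              "direction", "moving_track", "track", "axon",
                              "mouse", "dataset")}
    for tr in trackset:
        t = tr.times_s
        x = tr.positions_um
        dt = np.diff(t)
        v = (np.diff(x) / dt) * o
        n = len(v)
        net = tr.net_displacement_um * o
        cols["t_mid_s"].append((t[:-1] + t[1:]) / 2)
        cols["x_mid_um"].append((x[:-1] + x[1:]) / 2)
        cols["v_um_s"].append(v)
        cols["duration_s"].append(dt)
        cols["direction"].append(np.repeat(
            "antero" if net > 0 else ("retro" if net < 0 else "none"), n))
        cols["moving_track"].append(np.repeat(
            classify_moving(tr, DEFAULT_MOVING_THRESHOLD_UM), n))
        cols["track"].append(np.repeat(tr.track_id, n))
        cols["axon"].append(np.repeat(tr.axon_id, n))
        cols["mouse"].append(np.repeat(tr.mouse_id, n))
        cols["dataset"].append(np.repeat(tr.dataset_id, n))
    if not cols["v_um_s"]:
        return pd.DataFrame(columns=list(cols) + ["speed", "location",
                                                  "activity", "epoch"])
    df = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    df["speed"] = df["v_um_s"].abs()
    df["location"] = "shaft"
    df["activity"] = "rest"
    df["epoch"] = "none"
    return df


@dataclass
class EnrichmentResult:
    """Observed vs expected pause counts inside a synapse mask."""

    observed: int
    expected: float
    factor: float
    mask_fraction: float
    inner_um: float
    outer_um: float
    pause_threshold_um_s: float
    n_pauses_total: int


def pause_enrichment(samples: pd.DataFrame, mask: SynapseMask,
                     pause_threshold_um_s: float = 0.0) -> EnrichmentResult:
    """Pause enrichment factor = (pauses in mask / total pauses) / mask fraction.

    A pause sample is a segment with speed ≤ the pause definition (exactly 0
    when the threshold is 0); it is located by its position midpoint.  A
    factor of 1 means pauses occur in the mask exactly as often as expected
    if they were uniform along the axon; NaN when there are no pauses.
    """
    pauses = samples[samples["speed"] <= pause_threshold_um_s]
    total = len(pauses)
    if total == 0:
        return EnrichmentResult(0, 0.0, np.nan, mask.mask_fraction,
                                mask.inner_um, mask.outer_um,
                                pause_threshold_um_s, 0)
    obs = int(mask.contains(pauses["x_mid_um"].to_numpy()).sum())
    expected = total * mask.mask_fraction
    factor = (obs / total) / mask.mask_fraction if mask.mask_fraction > 0 else np.nan
    return EnrichmentResult(obs, expected, factor, mask.mask_fraction,
                            mask.inner_um, mask.outer_um,
                            pause_threshold_um_s, total)


def label_location(samples: pd.DataFrame, mask: SynapseMask) -> pd.DataFrame:
    """Label each sample synapse/shaft by its position midpoint."""
    out = samples.copy()
    inside = mask.contains(out["x_mid_um"].to_numpy())
    out["location"] = np.where(inside, "synapse", "shaft")
    return out


@dataclass
class ActivityTrace:
    """ΔF/F series with half-max active-state labelling.

    ``dff`` is (F−F0)/F0 with F0 the mean of frames at or below the baseline
    percentile; the active threshold is half the maximum of the 3-frame
    median-smoothed ΔF/F (robust to single-frame noise).
    """

    dff: np.ndarray
    frame_interval_s: float
    baseline_percentile: float
    threshold: float
    active: np.ndarray  # unextended active frames

    @property
    def n_frames(self) -> int:
        return len(self.dff)

    @property
    def active_time_ratio(self) -> float:
        return float(self.active.mean())


def compute_dff(raw: np.ndarray, frame_interval_s: float,
                baseline_percentile: float = 20.0,
                smooth_frames: int = 3) -> ActivityTrace:
    """ΔF/F from a raw fluorescence series with percentile baseline.

    F0 is the mean of frames at/below the `baseline_percentile` of the
    series; an error is raised when F0 ≤ 0 (ΔF/F undefined).  The half-max
    threshold uses the median-smoothed trace; a constant series yields
    threshold 0 and no active frames.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) < 2:
        raise ValueError("need ≥2 frames")
    f0 = raw[raw <= np.percentile(raw, baseline_percentile)].mean()
    if f0 <= 0:
        raise ValueError("baseline F0 ≤ 0; ΔF/F undefined")
    dff = (raw - f0) / f0
    smooth = median_filter(dff, size=smooth_frames, mode="nearest") \
        if smooth_frames > 1 else dff
    peak = smooth.max()
    if peak <= 0:
        return ActivityTrace(dff, frame_interval_s, baseline_percentile, 0.0,
                             np.zeros(len(dff), dtype=bool))
    thr = 0.5 * peak
    return ActivityTrace(dff, frame_interval_s, baseline_percentile, thr,
                         smooth >= thr)


def active_state(trace: ActivityTrace, extension_s: float = 0.0
                 ) -> tuple[np.ndarray, float]:
    """Active frames with each maximal run extended forward by `extension_s`.

    Overlapping extended runs merge; returns the boolean series and the
    active-time ratio (active frames / total frames).  Extension is applied
    after the end of each activity run, mirroring post-activity windows.
    """
    act = trace.active.copy()
    if extension_s > 0 and act.any():
        ext = int(np.ceil(extension_s / trace.frame_interval_s))
        idx = np.flatnonzero(act)
        # run ends = indices whose successor is inactive
        ends = idx[np.flatnonzero(np.diff(np.concatenate([idx, [len(act) + 1]])) > 1)]
        for e in ends:
            act[e: min(e + ext + 1, len(act))] = True
    return act, float(act.mean())


def _bout_starts(active: np.ndarray) -> np.ndarray:
    a = active.astype(int)
    return np.flatnonzero(np.diff(np.concatenate([[0], a])) == 1)


def label_activity(samples: pd.DataFrame, active: np.ndarray,
                   frame_interval_s: float, mode: str = "state",
                   window_s: float = 5.0):
    """Label samples by activity state, or compare speeds around bout onsets.

    state mode: each sample is active/rest by the frame containing its time
    midpoint (bout starts are closed on the left: a sample exactly at a bout
    start is active).  Returns the labelled DataFrame.

    onset mode: per activity bout, the mean |v| of samples in [start−w, start)
    and [start, start+w); returns a DataFrame with one row per bout.
    """
    t = samples["t_mid_s"].to_numpy()
    if mode == "state":
        out = samples.copy()
        frame = np.clip((t / frame_interval_s).astype(int), 0, len(active) - 1)
        out["activity"] = np.where(active[frame], "active", "rest")
        return out
    if mode == "onset":
        rows = []
        speed = samples["speed"].to_numpy()
        for b in _bout_starts(active):
            t0 = b * frame_interval_s
            pre = (t >= t0 - window_s) & (t < t0)
            post = (t >= t0) & (t < t0 + window_s)
            rows.append({"bout_start_s": t0,
                         "pre_mean_speed": speed[pre].mean() if pre.any() else np.nan,
                         "post_mean_speed": speed[post].mean() if post.any() else np.nan,
                         "n_pre": int(pre.sum()), "n_post": int(post.sum())})
        return pd.DataFrame(rows)
    raise ValueError("mode must be 'state' or 'onset'")


def label_epoch(samples: pd.DataFrame, stim_start_s: float, stim_end_s: float,
                recording_end_s: float | None = None) -> pd.DataFrame:
    """Label samples before/during/after a stimulation epoch.

    'during' is the half-open interval [start, end) on the sample time
    midpoint.
    """
    if not 0 <= stim_start_s < stim_end_s:
        raise ValueError("need 0 ≤ start < end")
    if recording_end_s is not None and stim_end_s > recording_end_s:
        raise ValueError("stimulation end beyond recording end")
    out = samples.copy()
    t = out["t_mid_s"].to_numpy()
    out["epoch"] = np.where(t < stim_start_s, "before",
                            np.where(t < stim_end_s, "during", "after"))
    return out


def roi_trace(movie: Movie, path: AxonPath) -> np.ndarray:
    """Mean intensity along the axon path per frame (e.g. calcium channel)."""
    from .imgproc import build_kymograph
    kymo = build_kymograph(movie, path)
    return kymo.data.mean(axis=1)
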