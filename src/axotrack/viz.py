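"""Figure helpers: kymograph track overlays and enrichment bar charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .context import EnrichmentResult
from .imgproc import Kymograph
from .metrics import classify_moving
from .tracking import TrackSet

__all__ = ["plot_kymograph_overlay", "plot_enrichment_bars"]


def plot_kymograph_overlay(kymo: Kymograph, trackset: TrackSet, out_path,
                           pause_threshold_um_s: float = 0.1) -> None:
    """Kymograph with traced tracks overlaid.

    Anterograde tracks are drawn green, retrograde red, non-moving blue
    (requires an assigned orientation; unset orientation draws all tracks
    yellow).
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(kymo.data, cmap="gray", aspect="auto",
              extent=(0, kymo.length_um, kymo.n_frames * kymo.frame_interval_s,
                      0))
    o = trackset.orientation
    for tr in trackset:
        if o is None:
            color = "gold"
        elif not classify_moving(tr):
            color = "tab:blue"
        else:
            color = "tab:green" if tr.net_displacement_um * o > 0 else "tab:red"
        ax.plot(tr.positions_um, tr.times_s, color=color, lw=1.0)
    ax.set_xlabel("position along axon (µm)")
    ax.set_ylabel("time (s)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_enrichment_bars(results: list[EnrichmentResult], out_path) -> None:
    """Enrichment factor per mask band; the dashed line marks factor 1
    (observed pauses equal the uniform-pausing expectation)."""
    fig, ax = plt.subplots(figsize=(4, 3))
    labels = [f"{r.inner_um:g}–{r.outer_um:g} µm" for r in results]
    vals = [r.factor for r in results]
    ax.bar(np.arange(len(vals)), vals, color="tab:blue")
    ax.axhline(1.0, color="k", ls="--", lw=1)
    ax.set_xticks(np.arange(len(vals)), labels, rotation=30)
    ax.set_ylabel("pauses / predicted")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
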