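"""Shared fixtures: all synthetic, seeded, generated at test time."""

import numpy as np
import pandas as pd
import pytest

from axotrack import simgen
from axotrack.imgproc import Movie


def make_manual_truth(trajectories: dict[str, np.ndarray],
                      config: simgen.SimConfig) -> simgen.GroundTruth:
    """GroundTruth from hand-written trajectories {pid: positions per frame}."""
    rows = []
    for pid, pos in trajectories.items():
        for f, x in enumerate(pos):
            state = "pause"
            if f + 1 < len(pos) and pos[f + 1] != x:
                state = "run_antero" if pos[f + 1] > x else "run_retro"
            rows.append((pid, "npy", f, float(x), state))
    particles = pd.DataFrame(rows, columns=["particle_id", "marker", "frame",
                                            "position_um", "state"])
    T = config.n_frames
    return simgen.GroundTruth(particles, np.empty(0), np.zeros(T, bool), [],
                              np.zeros((T, 2), int),
                              pd.DataFrame(columns=["particle_id", "frame",
                                                    "side"]), config)


@pytest.fixture(scope="session")
def ci_sim():
    """One small rendered recording with default kinetics (session-cached)."""
    cfg = simgen.ci_preset(seed=42)
    movies, truth = simgen.simulate_axon_movie(cfg)
    return cfg, movies, truth


@pytest.fixture()
def static_spot_movie():
    """Noise-free movie with one stationary bright punctum."""
    frames = np.ones((10, 24, 40))
    frames[:, 12, 20] += 8.0
    return Movie(frames, pixel_size_um=0.2, frame_interval_s=1.0)


@pytest.fixture(scope="session")
def null_speed_samples():
    """Factory for nested-hierarchy speed samples with no condition effect."""
    def make(rng, n_mice=3, n_ds=2, n_tracks=5, n_seg=6,
             effect=0.0, condition="location", levels=("A", "B")):
        rows = []
        for m in range(n_mice):
            bm = rng.normal(0, 0.1)
            for d in range(n_ds):
                bd = rng.normal(0, 0.1)
                for t in range(n_tracks):
                    bt = rng.normal(0, 0.15)
                    for _ in range(n_seg):
                        lev = levels[int(rng.random() < 0.5)]
                        y = 1.0 + bm + bd + bt + rng.normal(0, 0.4)
                        if lev == levels[1]:
                            y += effect
                        rows.append((f"m{m}", f"d{d}", f"t{m}{d}{t}", y, lev))
        return pd.DataFrame(rows, columns=["mouse", "dataset", "track",
                                           "speed", condition])
    return make
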