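"""Synapse masks, pause enrichment, ΔF/F activity states, epoch labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from axotrack import context, imgproc, simgen
from axotrack.context import (ActivityTrace, active_state, build_synapse_mask,
                              compute_dff, detect_synapse_centers,
                              label_activity, label_epoch, label_location,
                              pause_enrichment, speed_samples)


def sample_df(x, v=None, t=None):
    n = len(x)
    return pd.DataFrame({
        "t_mid_s": np.arange(n, dtype=float) if t is None else np.asarray(t),
        "x_mid_um": np.asarray(x, float),
        "v_um_s": np.zeros(n) if v is None else np.asarray(v, float),
        "speed": np.zeros(n) if v is None else np.abs(v),
        "duration_s": np.ones(n),
        "direction": ["antero"] * n,
        "track": ["t0"] * n, "axon": ["a0"] * n,
        "mouse": ["m0"] * n, "dataset": ["d0"] * n,
    })


class TestSynapseMask:
    def test_single_center_disk_fraction(self):
        m = build_synapse_mask([50.0], 0.0, 0.5, 100.0)
        assert m.mask_fraction == pytest.approx(0.01)

    def test_overlapping_disks_counted_once(self):
        m = build_synapse_mask([10.0, 10.4], 0.0, 0.5, 100.0)
        assert m.mask_fraction == pytest.approx(1.4 / 100)

    def test_annulus_excludes_inner_disks_of_all_centers(self):
        m = build_synapse_mask([10.0, 11.0], 0.5, 1.5, 100.0)
        assert not m.contains([10.8])[0]  # inside the other center's core
        assert m.contains([12.0])[0]

    def test_fraction_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            centers = np.sort(rng.uniform(0, 60, 8))
            for inner, outer in ((0.0, 0.5), (0.5, 1.5), (1.5, 2.5)):
                m = build_synapse_mask(centers, inner, outer, 60.0)
                grid = np.arange(0, 60, 0.01) + 0.005
                assert abs(m.contains(grid).mean() - m.mask_fraction) < 1e-3

    @given(st.lists(st.floats(0, 60), min_size=1, max_size=6),
           st.floats(0.1, 3.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mask_fraction_monotone_in_outer_radius(self, centers, outer):
        m1 = build_synapse_mask(centers, 0.0, outer, 60.0)
        m2 = build_synapse_mask(centers, 0.0, outer + 0.5, 60.0)
        assert m2.mask_fraction >= m1.mask_fraction

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            build_synapse_mask([10.0], 1.0, 0.5, 60.0)


class TestDetectCenters:
    def test_two_gaussian_bumps_located(self):
        x = np.arange(0, 40, 0.2)
        prof = (np.exp(-((x - 10) ** 2) / 0.5) +
                np.exp(-((x - 30) ** 2) / 0.5))
        centers = detect_synapse_centers(0.2, prof)
        assert len(centers) == 2
        assert centers[0] == pytest.approx(10.0, abs=0.2)
        assert centers[1] == pytest.approx(30.0, abs=0.2)

    def test_flat_profile_yields_no_centers_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            centers = detect_synapse_centers(0.2, np.ones(100))
        assert len(centers) == 0

    def test_rendered_synapse_channel_recovers_known_centers(self):
        true = [8.0, 17.5, 30.0]
        cfg = simgen.SimConfig(seed=2, n_frames=60, synapse_centers_um=true,
                               markers={"npy": simgen.MarkerKinetics(
                                   n_particles=0)})
        truth = simgen.simulate_kinetics(cfg)
        movies = simgen.render_movies(truth, cfg)
        kymo = imgproc.build_kymograph(movies["synapse"],
                                       simgen.make_path(cfg))
        centers = detect_synapse_centers(kymo.col_spacing_um,
                                         kymo.data.mean(axis=0))
        assert len(centers) == 3
        assert np.abs(np.asarray(true) - centers).max() <= 0.3


class TestEnrichment:
    def test_factor_arithmetic(self):
        # mask fraction 0.1, 30 pauses, 6 in mask → factor 2
        m = build_synapse_mask([5.0], 0.0, 5.0, 100.0)
        x = np.concatenate([np.linspace(0.5, 9.5, 6),
                            np.linspace(20, 90, 24)])
        r = pause_enrichment(sample_df(x), m, 0.0)
        assert r.mask_fraction == pytest.approx(0.1)
        assert r.observed == 6
        assert r.factor == pytest.approx(2.0)

    def test_mask_covering_whole_axon_gives_factor_one(self):
        m = build_synapse_mask([30.0], 0.0, 40.0, 60.0)
        r = pause_enrichment(sample_df(np.linspace(1, 59, 40)), m, 0.0)
        assert r.factor == pytest.approx(1.0)

    def test_no_pauses_reports_missing(self):
        m = build_synapse_mask([10.0], 0.0, 0.5, 60.0)
        df = sample_df(np.linspace(0, 50, 20), v=np.ones(20))
        r = pause_enrichment(df, m, 0.0)
        assert np.isnan(r.factor)

    def test_observed_count_monotone_in_threshold_and_radius(self):
        cfg = simgen.SimConfig(seed=13, n_frames=200,
                               synapse_centers_um=[10.0, 30.0],
                               markers={"npy": simgen.MarkerKinetics(
                                   n_particles=20)})
        truth = simgen.simulate_kinetics(cfg)
        samples = speed_samples(simgen.truth_to_tracks(truth, cfg))
        obs_thr = []
        for thr in (0.0, 0.2, 0.5, 1.0):
            m = build_synapse_mask(truth.synapse_centers_um, 0.0, 1.5, 40.0)
            obs_thr.append(pause_enrichment(samples, m, thr).observed)
        assert obs_thr == sorted(obs_thr)
        obs_rad = []
        for outer in (0.5, 1.5, 2.5):
            m = build_synapse_mask(truth.synapse_centers_um, 0.0, outer, 40.0)
            obs_rad.append(pause_enrichment(samples, m, 0.2).observed)
        assert obs_rad == sorted(obs_rad)

    def test_coupled_pausing_slows_synapse_samples(self):
        cfg = simgen.SimConfig(seed=19, n_frames=300, axon_length_um=60.0,
                               synapse_centers_um=[10., 25., 40., 55.],
                               synapse_radius_um=1.0,
                               synapse_pause_multiplier=6.0,
                               markers={"npy": simgen.MarkerKinetics(
                                   n_particles=25)})
        truth = simgen.simulate_kinetics(cfg)
        samples = speed_samples(simgen.truth_to_tracks(truth, cfg))
        m = build_synapse_mask(truth.synapse_centers_um, 0.0, 1.0, 60.0)
        lab = label_location(samples, m)
        means = lab.groupby("location")["speed"].mean()
        assert means["synapse"] < means["shaft"]


class TestLocationLabel:
    def test_sample_at_center_is_synapse_and_far_is_shaft(self):
        m = build_synapse_mask([10.0, 20.0], 0.0, 0.5, 60.0)
        lab = label_location(sample_df([10.0, 23.0]), m)
        assert list(lab["location"]) == ["synapse", "shaft"]

    def test_every_sample_gets_exactly_one_label_per_category(self):
        cfg = simgen.SimConfig(seed=3, n_frames=100, calcium_bout_rate=0.02,
                               synapse_centers_um=[15.0])
        truth = simgen.simulate_kinetics(cfg)
        samples = speed_samples(simgen.truth_to_tracks(truth, cfg))
        m = build_synapse_mask(truth.synapse_centers_um, 0.0, 1.5, 40.0)
        lab = label_location(samples, m)
        lab = label_activity(lab, truth.active, cfg.frame_interval_s)
        lab = label_epoch(lab, 20.0, 50.0)
        assert set(lab["location"]) <= {"synapse", "shaft"}
        assert set(lab["activity"]) <= {"active", "rest"}
        assert set(lab["epoch"]) <= {"before", "during", "after"}
        assert lab[["location", "activity", "epoch"]].notna().all().all()


class TestDff:
    def test_peak_dff_value(self):
        raw = np.full(50, 100.0)
        raw[25] = 150.0
        tr = compute_dff(raw, 1.0, smooth_frames=1)
        assert tr.dff.max() == pytest.approx(0.5)

    def test_constant_series_has_no_active_frames(self):
        tr = compute_dff(np.full(30, 7.0), 1.0)
        assert tr.threshold == 0.0
        assert not tr.active.any()

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            compute_dff(np.array([-5.0, -5.0, 1.0]), 1.0)

    def test_simulated_bouts_recovered_with_high_jaccard(self):
        cfg = simgen.SimConfig(seed=5, n_frames=600, calcium_bout_rate=0.02,
                               bout_duration_mean_s=6.0, photon_scale=200.0)
        truth = simgen.simulate_kinetics(cfg)
        raw = simgen.calcium_raw_trace(truth, cfg)
        tr = compute_dff(raw, cfg.frame_interval_s)
        act, _ = active_state(tr)
        union = (act | truth.active).sum()
        assert union > 0
        assert (act & truth.active).sum() / union >= 0.8


class TestActiveState:
    def make_trace(self, active, dt=1.0):
        act = np.asarray(active, bool)
        return ActivityTrace(act.astype(float), dt, 20.0, 0.5, act)

    def test_ratio_without_extension(self):
        act = np.zeros(40, bool)
        act[5:15] = True
        _, ratio = active_state(self.make_trace(act), 0.0)
        assert ratio == pytest.approx(10 / 40)

    def test_extension_appends_and_merges_runs(self):
        act = np.zeros(40, bool)
        act[5:15] = True
        ext, ratio = active_state(self.make_trace(act), 5.0)
        assert ratio == pytest.approx(15 / 40)
        act2 = np.zeros(40, bool)
        act2[5:10] = True
        act2[12:17] = True  # gap of 2 < extension → merged
        ext2, _ = active_state(self.make_trace(act2), 5.0)
        assert ext2[10:12].all()

    def test_extension_nesting_property(self):
        cfg = simgen.SimConfig(seed=7, n_frames=400, calcium_bout_rate=0.02)
        truth = simgen.simulate_kinetics(cfg)
        raw = simgen.calcium_raw_trace(truth, cfg)
        tr = compute_dff(raw, cfg.frame_interval_s)
        a0, _ = active_state(tr, 0.0)
        a5, _ = active_state(tr, 5.0)
        a30, _ = active_state(tr, 30.0)
        assert np.all(a0 <= a5) and np.all(a5 <= a30)


class TestActivityLabel:
    def test_all_samples_outside_active_are_rest(self):
        act = np.zeros(50, bool)
        lab = label_activity(sample_df([1, 2, 3], t=[5, 10, 20]), act, 1.0)
        assert (lab["activity"] == "rest").all()

    def test_sample_exactly_at_bout_start_is_active(self):
        act = np.zeros(50, bool)
        act[10:20] = True
        lab = label_activity(sample_df([1, 1], t=[10.0, 9.99]), act, 1.0)
        assert list(lab["activity"]) == ["active", "rest"]

    def test_onset_mode_returns_pre_post_bout_means(self):
        act = np.zeros(60, bool)
        act[30:40] = True
        df = sample_df(np.ones(60), v=np.r_[np.ones(30), 2 * np.ones(30)],
                       t=np.arange(60, dtype=float))
        out = label_activity(df, act, 1.0, mode="onset", window_s=5.0)
        assert len(out) == 1
        assert out["pre_mean_speed"].iloc[0] == pytest.approx(1.0)
        assert out["post_mean_speed"].iloc[0] == pytest.approx(2.0)

    def test_speed_increase_during_activity_detected_in_most_replicates(self):
        # power-style check at roughly one recording's worth of samples
        wins = 0
        for seed in range(30):
            cfg = simgen.SimConfig(
                seed=seed, n_frames=240, axon_length_um=80.0,
                calcium_bout_rate=0.021, bout_duration_mean_s=5.0,
                active_speed_multiplier=1.1,
                markers={"npy": simgen.MarkerKinetics(n_particles=16)})
            truth = simgen.simulate_kinetics(cfg)
            samples = speed_samples(simgen.truth_to_tracks(truth, cfg))
            lab = label_activity(samples, truth.active, cfg.frame_interval_s)
            moving = lab[lab["speed"] > 0.1]
            diff = moving[moving.activity == "active"]["speed"].mean() - \
                moving[moving.activity == "rest"]["speed"].mean()
            wins += diff > 0
        assert wins >= 27


class TestEpochLabel:
    def test_boundary_conventions(self):
        df = sample_df([1, 1, 1, 1], t=[19.0, 20.0, 49.99, 50.0])
        lab = label_epoch(df, 20.0, 50.0)
        assert list(lab["epoch"]) == ["before", "during", "during", "after"]

    def test_labels_partition_all_samples(self):
        rng = np.random.default_rng(0)
        df = sample_df(np.ones(100), t=rng.uniform(0, 100, 100))
        lab = label_epoch(df, 30.0, 60.0)
        counts = lab["epoch"].value_counts()
        assert counts.sum() == 100

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            label_epoch(sample_df([1.0]), 50.0, 20.0)
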