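"""Trafficking metrics: moving classification, orientation, speeds, flux,
axon inclusion, co-movement."""

import dataclasses

import numpy as np
import pytest

from axotrack import metrics, simgen
from axotrack.tracking import Track, TrackSet


def track(positions, dt=1.0, **kw):
    return Track(np.arange(len(positions)), np.asarray(positions, float),
                 frame_interval_s=dt, **kw)


def trackset(tracks, L=60.0, minutes=2.0, orientation=None):
    return TrackSet(list(tracks), axon_length_um=L, duration_min=minutes,
                    orientation=orientation)


class TestClassifyMoving:
    def test_large_net_displacement_is_moving(self):
        assert metrics.classify_moving(track(np.linspace(0, 10, 11)))

    def test_stationary_jitter_is_not_moving(self):
        rng = np.random.default_rng(0)
        jitter = 20 + 0.3 * rng.uniform(-1, 1, 30)
        assert not metrics.classify_moving(track(jitter))

    def test_classification_accuracy_on_mixed_population(self):
        # mobile + permanently paused markers, truth labels from the states
        mobile = simgen.MarkerKinetics(n_particles=60)
        frozen = simgen.MarkerKinetics(n_particles=60, pause_entry_rate=50.0,
                                       pause_exit_rate=1e-9)
        cfg = simgen.SimConfig(n_frames=120, axon_length_um=100.0, seed=17,
                               markers={"mob": mobile, "frz": frozen})
        truth = simgen.simulate_kinetics(cfg)
        correct = total = 0
        for marker, label in (("mob", True), ("frz", False)):
            ts = simgen.truth_to_tracks(truth, cfg, marker=marker)
            for tr in ts:
                truly_moving = label and abs(tr.net_displacement_um) > 0.5
                if marker == "frz":
                    truly_moving = False
                total += 1
                correct += metrics.classify_moving(tr) == truly_moving
        assert correct / total >= 0.95


class TestAssignDirection:
    def test_comets_toward_increasing_arc_set_plus_orientation(self):
        comets = trackset([track(np.linspace(0, 8, 10)),
                           track(np.linspace(5, 15, 10))])
        ts = trackset([track(np.linspace(0, 5, 10))])
        out = metrics.assign_direction(ts, comets)
        assert out.orientation == 1

    def test_faster_direction_labelled_anterograde_without_comets(self):
        # mean speeds 2.37 vs 1.48 µm/s → the faster side is anterograde
        fast = [track(np.arange(10) * 2.37) for _ in range(3)]
        slow = [track(30 - np.arange(10) * 1.48) for _ in range(3)]
        out = metrics.assign_direction(trackset(fast + slow, L=80.0))
        assert out.orientation == 1
        flipped = [track(80 - tr.positions_um) for tr in fast + slow]
        out2 = metrics.assign_direction(trackset(flipped, L=80.0))
        assert out2.orientation == -1

    def test_comet_channel_recovers_generator_orientation_always(self):
        # oracle: the generator's anterograde direction is +1 by construction
        hits = 0
        for seed in range(100):
            comet = simgen.MarkerKinetics(n_particles=4, p_anterograde=1.0)
            cfg = simgen.SimConfig(n_frames=60, seed=seed,
                                   markers={"comet": comet})
            truth = simgen.simulate_kinetics(cfg)
            comets = simgen.truth_to_tracks(truth, cfg, marker="comet")
            ts = trackset([track(np.linspace(0, 5, 10))],
                          L=cfg.axon_length_um)
            hits += metrics.assign_direction(ts, comets).orientation == 1
        assert hits == 100

    def test_tied_speeds_without_comets_leaves_orientation_unset(self):
        a = track(np.arange(10) * 1.0)
        b = track(20 - np.arange(10) * 1.0)
        with pytest.warns(UserWarning, match="tied"):
            out = metrics.assign_direction(trackset([a, b]))
        assert out.orientation is None


class TestSummarizeTracks:
    def test_equal_duration_segments_mean_speed_and_pause_fraction(self):
        tr = track([0.0, 1.0, 2.0, 2.0])  # |v| = 1,1,0 at 1 s each
        ts = trackset([tr], orientation=1)
        tab = metrics.summarize_tracks(ts, pause_threshold_um_s=0.1)
        assert tab["mean_moving_speed_um_s"].iloc[0] == pytest.approx(1.0)
        assert tab["pause_fraction"].iloc[0] == pytest.approx(1 / 3)

    def test_fully_paused_track_reports_missing_speed(self):
        tr = track([5.0] * 6)
        tab = metrics.summarize_tracks(trackset([tr], orientation=1))
        assert np.isnan(tab["mean_moving_speed_um_s"].iloc[0])
        assert tab["pause_fraction"].iloc[0] == 1.0

    def test_include_pauses_mode_lowers_mean_speed(self):
        tr = track([0.0, 1.0, 2.0, 2.0])
        ts = trackset([tr], orientation=1)
        excl = metrics.summarize_tracks(ts)["mean_moving_speed_um_s"].iloc[0]
        incl = metrics.summarize_tracks(
            ts, include_pauses_in_speed=True)["mean_moving_speed_um_s"].iloc[0]
        assert incl < excl

    def test_direction_recovery_at_generator_speed_means(self):
        mk = simgen.MarkerKinetics(n_particles=200, speed_mean_antero=1.5,
                                   speed_mean_retro=1.1)
        cfg = simgen.SimConfig(n_frames=150, axon_length_um=150.0,
                               markers={"npy": mk}, seed=23)
        truth = simgen.simulate_kinetics(cfg)
        ts = simgen.truth_to_tracks(truth, cfg)
        tab = metrics.summarize_tracks(ts)
        mv = tab[tab["moving"]]
        means = mv.groupby("direction")["mean_moving_speed_um_s"].mean()
        assert means["antero"] == pytest.approx(1.5, rel=0.05)
        assert means["retro"] == pytest.approx(1.1, rel=0.05)

    def test_orientation_flip_swaps_direction_summaries_exactly(self):
        cfg = simgen.SimConfig(n_frames=100, seed=31)
        truth = simgen.simulate_kinetics(cfg)
        ts = simgen.truth_to_tracks(truth, cfg)
        t1 = metrics.summarize_tracks(ts)
        t2 = metrics.summarize_tracks(dataclasses.replace(ts, orientation=-1))
        swap = {"antero": "retro", "retro": "antero", "none": "none"}
        assert list(t2["direction"]) == [swap[d] for d in t1["direction"]]
        assert np.allclose(t1["mean_moving_speed_um_s"],
                           t2["mean_moving_speed_um_s"], equal_nan=True)


class TestFlux:
    def test_relative_flux_is_fraction_of_anterograde_movers(self):
        ants = [track(np.linspace(0, 5, 8)) for _ in range(6)]
        rets = [track(np.linspace(20, 15, 8)) for _ in range(4)]
        ts = trackset(ants + rets, orientation=1)
        tab = metrics.summarize_tracks(ts)
        fx = metrics.compute_flux(ts, tab)
        assert fx.relative_flux_antero == pytest.approx(0.6)
        assert fx.relative_flux_antero + fx.relative_flux_retro == 1.0

    def test_absolute_flux_arithmetic(self):
        # 12 movers / 40 µm / 10 min = 0.03 organelles/µm/min
        tracks = [track(np.linspace(0, 5, 8)) for _ in range(12)]
        ts = trackset(tracks, L=40.0, minutes=10.0, orientation=1)
        fx = metrics.compute_flux(ts, metrics.summarize_tracks(ts))
        assert fx.absolute_flux == pytest.approx(0.03)

    def test_zero_movers_reports_missing_not_zero(self):
        ts = trackset([track([5.0] * 8)], orientation=1)
        fx = metrics.compute_flux(ts, metrics.summarize_tracks(ts))
        assert np.isnan(fx.relative_flux_antero)
        assert np.isnan(fx.absolute_flux)

    def test_flux_halves_when_duration_doubles(self):
        tracks = [track(np.linspace(0, 5, 8)) for _ in range(4)]
        ts1 = trackset(tracks, minutes=5.0, orientation=1)
        ts2 = trackset(tracks, minutes=10.0, orientation=1)
        tab = metrics.summarize_tracks(ts1)
        f1 = metrics.compute_flux(ts1, tab).absolute_flux
        f2 = metrics.compute_flux(ts2, tab).absolute_flux
        assert f1 == pytest.approx(2 * f2)

    def test_relative_flux_recovers_generator_p_anterograde(self):
        mk = simgen.MarkerKinetics(n_particles=300, p_anterograde=0.61)
        cfg = simgen.SimConfig(n_frames=120, axon_length_um=200.0,
                               markers={"npy": mk}, seed=29, reinject=False)
        truth = simgen.simulate_kinetics(cfg)
        ts = simgen.truth_to_tracks(truth, cfg)
        fx = metrics.compute_flux(ts, metrics.summarize_tracks(ts))
        ci = 3 * np.sqrt(0.61 * 0.39 / fx.n_moving)
        assert abs(fx.relative_flux_antero - 0.61) < ci


class TestFilterAxons:
    def test_three_movers_with_both_directions_included(self):
        good = trackset([track(np.linspace(0, 5, 8)),
                         track(np.linspace(10, 16, 8)),
                         track(np.linspace(30, 25, 8))])
        assert metrics.filter_axons({"ax1": {"npy": good}}) == ["ax1"]

    def test_three_movers_all_one_direction_excluded(self):
        bad = trackset([track(np.linspace(i, i + 6, 8)) for i in (0, 10, 20)])
        assert metrics.filter_axons({"ax1": {"npy": bad}}) == []

    def test_rule_requires_every_marker_to_pass(self):
        good = trackset([track(np.linspace(0, 5, 8)),
                         track(np.linspace(10, 16, 8)),
                         track(np.linspace(30, 25, 8))])
        sparse = trackset([track(np.linspace(0, 5, 8))])
        axons = {"a": {"m1": good, "m2": good},
                 "b": {"m1": good, "m2": sparse}}
        assert metrics.filter_axons(axons) == ["a"]

    def test_matches_brute_force_recount_on_random_sets(self):
        rng = np.random.default_rng(7)
        axons = {}
        for a in range(12):
            per_marker = {}
            for m in ("x", "y"):
                trs = []
                for t in range(int(rng.integers(1, 7))):
                    sign = 1 if rng.random() < 0.5 else -1
                    dist = rng.uniform(0, 6)
                    start = rng.uniform(10, 30)
                    trs.append(track(start + sign * np.linspace(0, dist, 8)))
                per_marker[m] = trackset(trs)
            axons[f"a{a}"] = per_marker
        got = metrics.filter_axons(axons)
        expected = []
        for aid, pm in axons.items():
            ok = True
            for ts in pm.values():
                signs = [np.sign(tr.net_displacement_um) for tr in ts
                         if abs(tr.net_displacement_um) >= 2.0]
                if len(signs) < 3 or 1 not in signs or -1 not in signs:
                    ok = False
            if ok:
                expected.append(aid)
        assert got == expected


class TestCoMovement:
    def test_identical_tracksets_fully_matched(self):
        ts = trackset([track(np.linspace(0, 8, 20)),
                       track(np.linspace(20, 12, 20))])
        fa, fb = metrics.co_movement_fraction(ts, ts)
        assert fa == 1.0 and fb == 1.0

    def test_disjoint_positions_unmatched(self):
        a = trackset([track(np.linspace(0, 5, 20))])
        b = trackset([track(np.linspace(30, 35, 20))])
        fa, fb = metrics.co_movement_fraction(a, b)
        assert fa == 0.0 and fb == 0.0

    def test_independent_channels_rarely_co_move(self):
        # null simulation: two independently simulated markers
        cfg = simgen.SimConfig(
            n_frames=150, axon_length_um=80.0, seed=37,
            markers={"m1": simgen.MarkerKinetics(n_particles=10),
                     "m2": simgen.MarkerKinetics(n_particles=10)})
        truth = simgen.simulate_kinetics(cfg)
        a = simgen.truth_to_tracks(truth, cfg, marker="m1")
        b = simgen.truth_to_tracks(truth, cfg, marker="m2")
        fa, fb = metrics.co_movement_fraction(a, b)
        assert fa < 0.05 and fb < 0.05
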