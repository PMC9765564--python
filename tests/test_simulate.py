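import dataclasses

import numpy as np
import pytest
from scipy import stats

import swimtrack as st
from swimtrack import MODES
from swimtrack.simulate import (
    front_speed,
    render_detections,
    simulate_division_clusters,
    simulate_population,
    simulate_spreading,
    simulate_swimmer,
)


class TestSimulateSwimmer:
    def test_deterministic_given_seed(self, wt, agar25):
        a = simulate_swimmer(wt, agar25, 5.0, 0.05, seed=42)
        b = simulate_swimmer(wt, agar25, 5.0, 0.05, seed=42)
        assert np.array_equal(a.xy, b.xy)
        assert np.array_equal(a.mode, b.mode)
        assert np.array_equal(a.phase, b.phase)

    def test_double_mutant_never_moves(self, double_mutant, bulk, agar25):
        for env in (bulk, agar25):
            p = simulate_swimmer(double_mutant, env, 10.0, 0.05, seed=1)
            assert p.path_length == 0.0

    def test_zero_duration_single_point_at_origin(self, wt, bulk):
        p = simulate_swimmer(wt, bulk, 0.0, 0.05, seed=0)
        assert len(p) == 1
        assert np.array_equal(p.xy, [[0.0, 0.0]])

    def test_dt_not_smaller_than_duration_rejected(self, wt, bulk):
        with pytest.raises(ValueError):
            simulate_swimmer(wt, bulk, 1.0, 1.0, seed=0)

    def test_stop_and_trap_timepoints_do_not_translate(self, wt, agar25):
        p = simulate_swimmer(wt, agar25, 30.0, 0.05, seed=3)
        step = np.linalg.norm(np.diff(p.xy, axis=0), axis=1)
        still = (p.mode[:-1] == "stop") | (p.phase[:-1] == "trap")
        assert np.all(step[still] == 0.0)

    def test_wrapped_steps_slower_than_push_steps(self, wt, bulk):
        p = simulate_swimmer(wt, bulk, 30.0, 0.05, seed=4)
        v = np.linalg.norm(np.diff(p.xy, axis=0), axis=1) / p.dt
        free = p.phase[:-1] == "run"
        push = v[(p.mode[:-1] == "push") & free]
        wrapped = v[(p.mode[:-1] == "wrapped") & free]
        assert push.size and wrapped.size
        assert wrapped.max() < push.min()

    def test_mode_marginal_matches_stationary_chi2(self, wt, bulk):
        # the chain starts in its stationary law, so a single timepoint
        # sampled from many independent paths is a clean iid draw
        n = 1500
        paths = simulate_population(n, wt, bulk, 2.0, 0.05, seed=9)
        modes = np.array([p.mode[20] for p in paths])
        counts = np.array([(modes == m).sum() for m in MODES])
        expected = n * wt.stationary_distribution(bulk.load)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=len(MODES) - 1) > 1e-4

    def test_population_mean_run_speed_matches_mixture(self, wt, bulk):
        # grand mean chord speed over run-mode frames vs the closed-form
        # stationary mixture, within 2 Monte-Carlo SEM across paths
        paths = simulate_population(500, wt, bulk, 10.0, 0.05, seed=10)
        per_path = []
        for p in paths:
            v = np.linalg.norm(np.diff(p.xy, axis=0), axis=1) / p.dt
            run = p.mode[:-1] != "stop"
            if run.any():
                per_path.append(v[run].mean())
        per_path = np.array(per_path)
        sem = per_path.std(ddof=1) / np.sqrt(len(per_path))
        assert abs(per_path.mean() - wt.run_speed_mean(bulk)) < 2 * sem


class TestSimulatePopulation:
    def test_zero_paths(self, wt, bulk):
        assert simulate_population(0, wt, bulk, 1.0, 0.05, seed=0) == []

    def test_reproducible_from_master_seed(self, wt, agar25):
        a = simulate_population(10, wt, agar25, 2.0, 0.05, seed=5)
        b = simulate_population(10, wt, agar25, 2.0, 0.05, seed=5)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.xy, pb.xy)

    def test_agar_traps_more_than_bulk(self, wt, bulk, agar25):
        agar_paths = simulate_population(200, wt, agar25, 10.0, 0.05, seed=6)
        bulk_paths = simulate_population(200, wt, bulk, 10.0, 0.05, seed=6)
        frac = lambda ps: np.mean([np.mean(p.phase == "trap") for p in ps])
        assert frac(bulk_paths) == 0.0
        assert frac(agar_paths) > 0.05

    def test_tighter_pores_trap_more(self, wt, agar25):
        tighter = dataclasses.replace(agar25, pore_range_nm=(400.0, 1500.0))
        loose = simulate_population(100, wt, agar25, 10.0, 0.05, seed=7)
        tight = simulate_population(100, wt, tighter, 10.0, 0.05, seed=7)
        frac = lambda ps: np.mean([np.mean(p.phase == "trap") for p in ps])
        assert frac(tight) > frac(loose)


class TestRenderDetections:
    def test_noiseless_perfect_detection_reproduces_truth(self, wt, bulk):
        paths = simulate_population(5, wt, bulk, 2.0, 0.05, seed=8)
        dets = render_detections(paths, sigma_loc=0.0, p_detect=1.0,
                                 fp_per_frame=0.0, seed=0)
        truth = st.paths_to_dataframe(paths)
        assert len(dets.df) == len(truth)
        merged = dets.df.sort_values(["frame", "truth_id"]).reset_index()
        truth = truth.sort_values(["frame", "track_id"]).reset_index()
        assert np.allclose(merged["x_um"], truth["x_um"])
        assert np.allclose(merged["y_um"], truth["y_um"])

    def test_zero_detection_probability_leaves_only_false_positives(self, wt, bulk):
        paths = simulate_population(5, wt, bulk, 2.0, 0.05, seed=8)
        dets = render_detections(paths, p_detect=0.0, fp_per_frame=1.0, seed=1)
        assert (dets.df["truth_id"] == -1).all()

    def test_localization_noise_rms(self, double_mutant, bulk):
        # 2-D isotropic Gaussian with sigma per axis has RMS radius sigma*sqrt(2)
        paths = simulate_population(100, double_mutant, bulk, 5.0, 0.05, seed=2,
                                    box=(-500, 500, -500, 500))
        dets = render_detections(paths, sigma_loc=0.1, p_detect=1.0,
                                 fp_per_frame=0.0, seed=3)
        truth = {p.id: p.xy[0] for p in paths}
        df = dets.df
        dev = np.array(
            [df["x_um"] - [truth[i][0] for i in df["truth_id"]],
             df["y_um"] - [truth[i][1] for i in df["truth_id"]]]
        )
        rms = np.sqrt((dev**2).sum(axis=0).mean())
        assert len(df) >= 10_000
        assert rms == pytest.approx(0.1 * np.sqrt(2.0), rel=0.05)

    def test_empty_fov_rejected(self, wt, bulk):
        paths = simulate_population(2, wt, bulk, 1.0, 0.05, seed=0)
        with pytest.raises(ValueError):
            render_detections(paths, fov=(0.0, 0.0, -1.0, 1.0))


class TestDivisionClusters:
    def test_all_motile_daughters_no_clusters(self, wt, bulk):
        strain = dataclasses.replace(wt, p_motile_daughter={"bulk": 1.0})
        records, summary = simulate_division_clusters(strain, bulk, 5, 5.0, seed=0)
        assert summary["n_clusters"].max() == 0
        assert all(r.daughters == ("motile", "motile") for r in records)

    def test_fully_sessile_growth_matches_branching_mean(self, wt, agar25):
        # p_motile = 0, n0 = 1: E[N(t)] = e^{g t}, so after three doubling
        # times the single founding cluster holds 8 cells in expectation
        strain = dataclasses.replace(wt, p_motile_daughter={"agar_0.25": 0.0})
        t3 = 3.0 * np.log(2.0) / strain.division_rate
        sizes = []
        ss = np.random.SeedSequence(12).spawn(400)
        for child in ss:
            _, summary = simulate_division_clusters(strain, agar25, 1, t3,
                                                    seed=np.random.default_rng(child))
            sizes.append(summary["largest_cluster"].iloc[-1])
        sizes = np.array(sizes, dtype=float)
        sem = sizes.std(ddof=1) / np.sqrt(len(sizes))
        assert abs(sizes.mean() - 8.0) < 3 * sem

    def test_motcd_loses_motile_cells_faster_than_motab(self, motab, motcd, envs):
        agar30 = envs["agar_0.30"]
        _, s_cd = simulate_division_clusters(motcd, agar30, 50, 4.0, seed=3)
        _, s_ab = simulate_division_clusters(motab, agar30, 50, 4.0, seed=3)
        frac = lambda s: s["n_motile"].iloc[-1] / (
            s["n_motile"].iloc[-1] + s["n_sessile"].iloc[-1]
        )
        assert frac(s_cd) < frac(s_ab)


class TestSpreading:
    def test_nonmotile_strain_never_spreads(self, double_mutant, agar25):
        series = simulate_spreading(double_mutant, agar25, 24.0)
        assert np.all(series.diameter_mm == series.diameter_mm[0])

    def test_front_speed_square_root_law(self, wt, agar25):
        # doubling D_eff * g_eff scales the front speed by sqrt(2); here the
        # growth term is doubled through the division rate
        doubled = dataclasses.replace(wt, division_rate=2 * wt.division_rate)
        assert front_speed(doubled, agar25) == pytest.approx(
            np.sqrt(2.0) * front_speed(wt, agar25), rel=1e-12
        )

    def test_slope_monotone_in_motile_daughter_probability(self, wt, agar25):
        speeds = []
        for p in (0.1, 0.5, 0.9):
            s = dataclasses.replace(wt, p_motile_daughter={"agar_0.25": p})
            speeds.append(front_speed(s, agar25))
        assert speeds == sorted(speeds)

    def test_noise_keeps_diameter_non_decreasing(self, wt, agar25):
        series = simulate_spreading(wt, agar25, 24.0, seed=5, noise_mm=0.3)
        assert np.all(np.diff(series.diameter_mm) >= 0)
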