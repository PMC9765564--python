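import itertools

import numpy as np
import pandas as pd
import pytest

import swimtrack as st
from swimtrack.tracking import LinkConfig, link_detections, track_recovery_score


def detections_table(rows):
    """rows: iterable of (frame, x, y)."""
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


def brute_force_link(df, config):
    """Independent sequential linker with exhaustive per-frame assignment.

    For every frame it enumerates all injective partial matchings between
    active track heads and detections, keeps only matchings whose links all
    respect the displacement gate, and picks the one with the most links
    and, among those, the minimum summed squared displacement.  Returns
    tracks as lists of (frame, x, y).
    """
    tracks = []  # list of dicts: {"pts": [(f,x,y)], "last_f": int}
    active = []
    for frame, grp in df.groupby("frame", sort=True):
        frame = int(frame)
        active = [t for t in active if frame - t["pts"][-1][0] - 1 <= config.memory]
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        nh, nd = len(active), len(pts)
        best = (0, 0.0, ())  # (-n_links, cost, matching)
        best_key = None
        for k in range(min(nh, nd), -1, -1):
            for hsub in itertools.combinations(range(nh), k):
                for dperm in itertools.permutations(range(nd), k):
                    cost = 0.0
                    ok = True
                    for hi, di in zip(hsub, dperm):
                        hx, hy = active[hi]["pts"][-1][1:]
                        d = np.hypot(pts[di, 0] - hx, pts[di, 1] - hy)
                        if d > config.max_disp:
                            ok = False
                            break
                        cost += d * d
                    if ok:
                        key = (-k, cost)
                        if best_key is None or key < best_key:
                            best_key = key
                            best = (k, cost, tuple(zip(hsub, dperm)))
            if best_key is not None and -best_key[0] == k:
                break  # no larger matching exists
        matched = set()
        for hi, di in best[2]:
            active[hi]["pts"].append((frame, pts[di, 0], pts[di, 1]))
            matched.add(di)
        for di in range(nd):
            if di not in matched:
                t = {"pts": [(frame, pts[di, 0], pts[di, 1])]}
                tracks.append(t)
                active.append(t)
    return [t["pts"] for t in tracks]


def as_point_sets(tracks_or_lists):
    out = []
    for t in tracks_or_lists:
        if hasattr(t, "frames"):
            out.append(tuple((f, round(x, 9), round(y, 9))
                             for f, x, y in zip(t.frames, t.x, t.y)))
        else:
            out.append(tuple((f, round(x, 9), round(y, 9)) for f, x, y in t))
    return sorted(out)


class TestLinkDetections:
    def test_static_detection_yields_single_track(self):
        df = detections_table([(f, 1.0, 2.0) for f in range(10)])
        tracks = link_detections(df, LinkConfig(max_disp=1.0))
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_distant_particles_never_cross_link(self):
        rows = []
        for f in range(10):
            rows += [(f, 0.0, 0.0), (f, 50.0, 0.0)]
        tracks = link_detections(detections_table(rows), LinkConfig(max_disp=5.0))
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_gap_closed_within_memory(self):
        rows = [(f, 0.1 * f, 0.0) for f in range(10) if f != 4]
        tracks = link_detections(detections_table(rows),
                                 LinkConfig(max_disp=1.0, memory=2))
        assert len(tracks) == 1
        assert 4 not in tracks[0].frames

    def test_track_terminates_beyond_memory(self):
        rows = [(f, 0.0, 0.0) for f in (0, 1, 2, 7, 8)]
        tracks = link_detections(detections_table(rows),
                                 LinkConfig(max_disp=1.0, memory=2))
        assert len(tracks) == 2

    def test_unordered_frames_rejected(self):
        df = detections_table([(3, 0.0, 0.0), (1, 0.0, 0.0)])
        with pytest.raises(ValueError):
            link_detections(df, LinkConfig())

    def test_no_link_exceeds_gate(self):
        rng = np.random.default_rng(0)
        rows = [(f, *rng.uniform(0, 30, 2)) for f in range(8) for _ in range(6)]
        config = LinkConfig(max_disp=2.5, memory=1)
        for t in link_detections(detections_table(rows), config):
            steps = np.diff(np.column_stack([t.x, t.y]), axis=0)
            assert np.all(np.linalg.norm(steps, axis=1) <= config.max_disp + 1e-9)

    def test_permutation_of_detections_within_frame_changes_no_link(self):
        rng = np.random.default_rng(1)
        rows = []
        pos = rng.uniform(0, 50, size=(4, 2))
        for f in range(6):
            pos = pos + rng.normal(0, 0.5, size=pos.shape)
            for p in pos:
                rows.append((f, p[0], p[1]))
        df = detections_table(rows)
        shuffled = (
            df.sample(frac=1, random_state=7)
            .sort_values("frame", kind="stable")
            .reset_index(drop=True)
        )
        a = link_detections(df, LinkConfig(max_disp=3.0))
        b = link_detections(shuffled, LinkConfig(max_disp=3.0))
        assert as_point_sets(a) == as_point_sets(b)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        pos = rng.uniform(0, 20, size=(n, 2))
        rows = []
        for f in range(6):
            keep = rng.random(n) < 0.9  # occasional missed detections
            for i in np.flatnonzero(keep):
                rows.append((f, pos[i, 0], pos[i, 1]))
            pos = pos + rng.normal(0, 0.8, size=pos.shape)
        df = detections_table(rows)
        config = LinkConfig(max_disp=3.0, memory=1)
        ours = link_detections(df, config)
        oracle = brute_force_link(df, config)
        assert as_point_sets(ours) == as_point_sets(oracle)


class TestRecoveryScore:
    def test_perfect_tracks_score_one(self, wt, bulk):
        paths = st.simulate_population(6, wt, bulk, 3.0, 0.05, seed=3,
                                       box=(-200, 200, -200, 200))
        dets = st.render_detections(paths, sigma_loc=0.0, p_detect=1.0,
                                    fp_per_frame=0.0, seed=4)
        tracks = link_detections(dets, LinkConfig(max_disp=5.0))
        assert track_recovery_score(tracks, dets) == 1.0

    def test_swapped_links_at_a_crossing_are_penalized(self):
        # two particles walking through each other: at the crossing the
        # minimal-displacement assignment swaps identities, and exactly
        # those two links score as wrong (8 of 10 links remain correct)
        rows, truth = [], []
        for f in range(6):
            rows.append((f, float(f), 0.0))
            truth.append(0)
            rows.append((f, 5.0 - f, 0.0))
            truth.append(1)
        df = detections_table(rows)
        df["truth_id"] = truth
        tracks = link_detections(df, LinkConfig(max_disp=1.5))
        assert track_recovery_score(tracks, df) == pytest.approx(0.8)

    def test_well_separated_population_recovers(self, wt, bulk):
        paths = st.simulate_population(40, wt, bulk, 5.0, 0.05, seed=5,
                                       box=(-600, 600, -600, 600))
        dets = st.render_detections(paths, fov=(-650, 650, -650, 650), seed=6,
                                    sigma_loc=0.05, p_detect=1.0, fp_per_frame=0.0)
        tracks = link_detections(dets, LinkConfig(max_disp=5.0))
        assert track_recovery_score(tracks, dets) >= 0.99

    def test_empty_input_rejected(self):
        df = detections_table([(0, 0.0, 0.0)])
        df["truth_id"] = [0]
        with pytest.raises(ValueError):
            track_recovery_score([], df)
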