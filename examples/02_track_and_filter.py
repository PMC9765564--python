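"""From noisy detections to quality-controlled trajectories.

Renders per-frame centroid detections of a synthetic population (with
localization noise, missed detections and false positives), links them back
into trajectories with the minimum-displacement assignment linker, scores
the links against ground truth, and applies the agar QC cascade.
"""

import swimtrack as st

strains, envs = st.load_default_profiles()
wt, agar = strains["wt"], envs["agar_0.25"]

paths = st.simulate_population(100, wt, agar, 15.0, dt=0.05, seed=2,
                               box=(-250, 250, -250, 250))
dets = st.render_detections(paths, sigma_loc=0.05, p_detect=0.97,
                            fp_per_frame=0.2, fov=(-260, 260, -260, 260), seed=3)
print(f"detections: {len(dets.df)} over {dets.n_frames} frames "
      f"({(dets.df['truth_id'] == -1).sum()} false positives)")

tracks = st.link_detections(dets, st.LinkConfig(max_disp=5.0, memory=2))
score = st.track_recovery_score(tracks, dets)
print(f"linked into {len(tracks)} tracks; "
      f"{score:.1%} of links connect the same true cell")

traj = st.tracks_to_dataframe(tracks, fps=20.0)
kept, report = st.filter_trajectories(traj, st.QCRuleSet.agar())
print(f"QC (agar dialect): kept {kept['track_id'].nunique()} tracks, "
      f"removed {len(report)}")
print(report["reason"].value_counts().to_string())
print(
    "\nRemovals are short fragments (false positives, dropout-split stubs);"
    "\nthe linker recovers essentially all true frame-to-frame links at"
    "\nthis density."
)
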