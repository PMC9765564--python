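"""Population speed statistics and mean-square displacement.

Compares the wild type with the MotAB knockout in bulk fluid: the knockout
swims several times more slowly, which shows up both in the whole-trajectory
speed summary and as a downward shift of the MSD curve / effective
diffusivity.
"""

import swimtrack as st

strains, envs = st.load_default_profiles()
bulk = envs["bulk"]
cols = ["track_id", "frame", "t_s", "x_um", "y_um"]

for name in ("wt", "d_motAB"):
    paths = st.simulate_population(150, strains[name], bulk, 10.0, dt=0.05,
                                   seed=4)
    traj = st.paths_to_dataframe(paths)[cols]
    summary = st.population_speed(traj, dialect="whole")
    msd = st.compute_msd(traj, max_lag=2.0)
    fit = st.estimate_diffusivity(msd, fit_range=(0.5, 2.0))
    print(f"{name:10s} mean speed {summary.mean:6.1f} +/- {summary.sem:.1f} um/s "
          f"(n={summary.n});  MSD slope/4 = {fit.D:8.1f} um^2/s"
          f"{'  [superdiffusive]' if fit.superdiffusive else ''}")

print(
    "\nThe knockout's whole-trajectory mean is far below a quarter of the"
    "\nwild type's, and its MSD-derived mobility collapses accordingly."
    "\nOn these short lags the wild type is still ballistic, so its slope/4"
    "\nis an effective mobility, not a true diffusivity (hence the flag)."
)
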