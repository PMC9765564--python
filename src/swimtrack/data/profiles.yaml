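# Default strain and environment profiles.
#
# Strains: wild type (wt), single stator knockouts (d_motAB, d_motCD) and the
# nonmotile double knockout (d_motAB_motCD).  Mode speeds are bulk-fluid run
# speeds in um/s; mode_speed_agar holds the run speeds inside semisolid agar,
# where stator remodelling makes the nearly-nonmotile d_motAB strain swim at
# wild-type-like speed.  Switch rates are continuous-time Markov rates (1/s)
# between push / pull / wrapped / stop; rates into the two clockwise modes
# (pull, wrapped) are re-split at simulation time by the load-dependent
# wrapped propensity.  Division rates are 1/h; p_motile_daughter maps an
# environment label to the probability that a daughter cell swims away after
# a trapped division.

strains:
  wt:
    mode_speed: {push: 38.0, pull: 32.0, wrapped: 21.0}
    mode_speed_agar: {push: 27.0, pull: 23.0, wrapped: 16.0}
    switch_rate:
      push: {pull: 0.18, wrapped: 0.12, stop: 0.25}
      pull: {push: 0.35, wrapped: 0.15, stop: 0.25}
      wrapped: {push: 0.25, stop: 0.25}
      stop: {push: 1.5, pull: 0.8, wrapped: 0.4}
    ccw_bias: 0.55
    wrapped_propensity_params: [1.5, 1.2, 1.0]   # midpoint cP, steepness, max
    propensity_shape: logistic
    rot_diffusion: 0.1
    division_rate: 0.9
    p_motile_daughter: {bulk: 1.0, "agar_0.25": 0.95, "agar_0.30": 0.90}
    reversal_jitter_deg: 15.0

  d_motAB:
    # MotAB missing: barely motile in fluids (short, erratic trajectories),
    # CCW-push biased, no wrapped mode in bulk, wrapped mode only at
    # intermediate load; near-wild-type speeds in agar.
    mode_speed: {push: 8.0, pull: 6.5, wrapped: 5.0}
    mode_speed_agar: {push: 24.0, pull: 20.0, wrapped: 14.0}
    switch_rate:
      push: {pull: 0.08, wrapped: 0.04, stop: 0.5}
      pull: {push: 0.5, wrapped: 0.05, stop: 0.5}
      wrapped: {push: 0.4, stop: 0.3}
      stop: {push: 1.5, pull: 0.4, wrapped: 0.1}
    ccw_bias: 0.75
    wrapped_propensity_params: [10.0, 0.8, 0.4]  # peak cP, log-width, max
    propensity_shape: peaked
    rot_diffusion: 1.5
    division_rate: 0.9
    p_motile_daughter: {bulk: 1.0, "agar_0.25": 0.90, "agar_0.30": 0.85}
    reversal_jitter_deg: 15.0

  d_motCD:
    # MotCD missing: indistinguishable from wild type in fluids, but daughters
    # of trapped cells in agar mostly stay sessile and form growing clusters.
    mode_speed: {push: 38.5, pull: 32.5, wrapped: 21.0}
    mode_speed_agar: {push: 30.0, pull: 26.0, wrapped: 18.0}
    switch_rate:
      push: {pull: 0.18, wrapped: 0.12, stop: 0.25}
      pull: {push: 0.35, wrapped: 0.15, stop: 0.25}
      wrapped: {push: 0.25, stop: 0.25}
      stop: {push: 1.5, pull: 0.8, wrapped: 0.4}
    ccw_bias: 0.55
    wrapped_propensity_params: [1.5, 1.2, 1.0]
    propensity_shape: logistic
    rot_diffusion: 0.1
    division_rate: 0.9
    p_motile_daughter: {bulk: 1.0, "agar_0.25": 0.30, "agar_0.30": 0.08}
    reversal_jitter_deg: 15.0

  d_motAB_motCD:
    # no stators, no torque: nonmotile
    mode_speed: {push: 0.0, pull: 0.0, wrapped: 0.0}
    mode_speed_agar: {push: 0.0, pull: 0.0, wrapped: 0.0}
    switch_rate:
      push: {pull: 0.18, wrapped: 0.12, stop: 0.25}
      pull: {push: 0.35, wrapped: 0.15, stop: 0.25}
      wrapped: {push: 0.25, stop: 0.25}
      stop: {push: 1.5, pull: 0.8, wrapped: 0.4}
    ccw_bias: 0.55
    wrapped_propensity_params: [1.5, 1.2, 0.0]
    propensity_shape: logistic
    rot_diffusion: 0.1
    division_rate: 0.9
    p_motile_daughter: {bulk: 0.0, "agar_0.25": 0.0, "agar_0.30": 0.0}
    reversal_jitter_deg: 15.0

environments:
  bulk:
    kind: bulk
    viscosity: 1.0
  ficoll_10:
    kind: bulk
    viscosity: 5.0
    ficoll_pct: 10.0
  ficoll_15:
    kind: bulk
    viscosity: 10.0
    ficoll_pct: 15.0
  ficoll_20:
    kind: bulk
    viscosity: 18.0
    ficoll_pct: 20.0
  "agar_0.25":
    kind: agar
    viscosity: 1.0          # fluid phase inside the pores
    agar_pct: 0.25
    pore_range_nm: [740.0, 4800.0]
    trap_rate: 0.15         # encounters per um at the 1000-nm reference pore
    trap_duration_mean: 1.0
    load_cP: 10.0           # meshwork load proxy on the bundle
  "agar_0.30":
    kind: agar
    viscosity: 1.0
    agar_pct: 0.30
    pore_range_nm: [500.0, 3000.0]
    trap_rate: 0.25
    trap_duration_mean: 1.5
    load_cP: 12.0
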