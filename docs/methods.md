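# Methods

This note documents the models behind `swimtrack`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic
validation does and does not demonstrate.

## Swimmer model

A swimmer is a point in two dimensions. Imaging-style data are single
focal planes (the standard assay records a plane ~30 µm above the surface
at 20 fps), so the model is planar throughout; out-of-plane excursions of
real cells appear in data as detection dropouts, which the detection
renderer emulates with a miss probability.

**Mode switching.** The motor state is a continuous-time Markov chain over
`{push, pull, wrapped, stop}`. Off-diagonal rates (1/s) are strain
parameters. Two load-dependent modifications are applied before
simulation:

* entries into the clockwise pair (pull, wrapped) from push or stop are
  pooled and re-split by the wrapped propensity `p_w(load)`, so load
  changes the pull/wrapped partition without changing the CW:CCW balance
  (matching the observation that the CW:CCW ratio stays roughly constant
  across viscosities while the wrapped share grows);
* the direct pull→wrapped rate (the wrapping instability of a pulling
  bundle) is multiplied by `p_w`, so a strain with `p_w = 0` at low load
  never wraps there.

`p_w(load)` is logistic in log-load for the wild type and the MotCD
knockout (midpoint 1.5 cP, steepness 1.2, max 1), reaching ~0.95 at 18 cP.
For the MotAB knockout it is a log-normal-shaped bump (peak at 10 cP,
log-width 0.8, max 0.4) with the load-1 baseline subtracted, encoding the
rise-and-fall of its wrapped share with exactly zero wrapping in plain
medium. "Load" is the fluid viscosity in bulk; agar environments carry a
load proxy (10–12 cP equivalent) because the meshwork loads the bundle far
beyond the 1-cP fluid in its pores.

**Translation.** During a run the cell advances at the mode speed times
the viscous slowdown factor `(η/1 cP)^(−α)`; the default α ≈ 0.56 is the
log–log least-squares slope through the wild-type mean-speed anchors
(1 cP, 32.1), (5, 11.4), (10, 8.9), (18, 6.3) µm/s. The heading diffuses
rotationally during runs (`rot_diffusion`, rad²/s); push↔pull switches
flip the heading by 180° plus Gaussian jitter (σ = 15°); other switches
keep the heading. Stops do not translate.

**Trapping (agar only).** Trap encounters fire as a Poisson process along
the run path with rate `trap_rate × (1000 nm / mean pore diameter)` per
µm, so tighter meshes trap more per unit path. A trapped cell does not
translate; release is drawn per frame with probability `dt/dwell` (a
geometric law whose mean equals the nominal exponential dwell exactly on
the grid), after which the cell leaves with a uniformly random heading.
The motor keeps switching modes in real time while the cell is wedged —
besides being the physically sensible choice (trapped cells visibly keep
trying to reorient), freezing the chain instead provably distorts the
run-frame mode composition under a fixed-length observation window.

**Discretization.** The chain is advanced per frame with switch
probabilities `q·dt`; since the stationary law of `I + Q·dt` equals that
of `Q`, occupancies are exact at any `dt` that keeps all row sums below 1
(asserted). Paths start in the stationary law, so time averages are
unbiased from the first frame. Default `dt = 0.05 s` (20 fps).

**What a run-speed measurement samples.** Because trap encounters scale
with speed, the *freely swimming* subpopulation is enriched in slow modes.
The package therefore computes the configured mean run speed from the
joint 8-state chain over (mode) × (free, trapped) — mode switching in both
trap states, entry at `λ_m = trap_rate_per_µm · v_m`, exit at `1/dwell` —
and uses the free-state occupancies. In bulk this reduces to the plain
stationary mixture. Comparing a measured run-speed mean against the bare
mode-chain mixture would be comparing against a quantity no measurement
estimates.

## Default profiles (the simulated study conditions)

Four strains ship as defaults. Wild type: bulk mode speeds 38/32/21 µm/s
(push/pull/wrapped), agar speeds 27/23/16 µm/s, rotational diffusion
0.1 rad²/s. MotAB knockout: barely motile in fluid (8/6.5/5 µm/s) with
high rotational diffusion (1.5 rad²/s — short, erratic trajectories) and a
push-biased chain (~69 % of runs CCW), but near-wild-type agar speeds
(24/20/14 µm/s): stator remodelling in the meshwork is encoded as
profile data (`mode_speed_agar`) because it is not derivable from the bulk
numbers. MotCD knockout: wild-type-like speeds everywhere, but daughters
of trapped cells in agar mostly stay sessile (motile-daughter probability
0.30 in 0.25 % agar, 0.08 in 0.30 %, vs ~0.9–0.95 for the other motile
strains). Double knockout: all speeds zero. Division rate 0.9/h for all
strains (growth is not affected by the knockouts). Switch rates give mean
run durations of order 1–2 s and stop durations of ~0.4 s; no measured
switching rates exist for these strains, so these are order-of-magnitude
choices exposed in `data/profiles.yaml`.

Environments: bulk (1 cP); Ficoll at 10/15/20 % ⇒ 5/10/18 cP via a
monotone (PCHIP) interpolation of log-viscosity through the printed
anchors, refusing extrapolation beyond 20 %; 0.25 % agar with pores
740–4800 nm, trap rate 0.15/µm at the 1000-nm reference pore and 1 s mean
dwell; 0.30 % agar with pores 500–3000 nm (chosen tighter; no printed
values exist), trap rate 0.25/µm, 1.5 s dwell.

## Analysis pipeline

**Detection and linking.** The renderer emits per-frame detections with
isotropic Gaussian localization noise (default σ = 0.05 µm), detection
probability 0.97 and 0.2 uniform false positives per frame. Linking
solves, per frame, the exact minimum-total-squared-displacement assignment
between active track heads and detections (Hungarian algorithm), forbids
links beyond `max_disp`, starts tracks from unmatched detections, and
keeps unmatched heads alive for `memory` frames (no motion prediction;
a head re-enters matching at its last position). Ties are broken by lowest
(track id, detection index). Defaults `max_disp = 3 µm`, `memory = 2` at
20 fps; the validation pipeline on agar populations uses 5 µm so that a
single dropped frame at ~24 µm/s (2×1.2 µm) remains linkable.

**QC.** Bulk cascade: mean speed < 10 µm/s, net displacement < 5 µm,
duration < 2 s, or straightness < 0.5 ⇒ removed (OR semantics, first
violated rule reported). Agar cascade: duration < 1.5 s or displacement
< 1 µm. Straightness is net displacement over path length (1 = straight,
0 = closed); the source criterion for "highly curved" is not public, so
the 0.5 default is config-exposed. "Displacement" is read as net
end-to-end displacement (the simplest reading). A zero-length path gets
straightness 0 by convention; the displacement rule removes it anyway.

**Run/trap segmentation.** Speeds are central finite differences over a
±1-frame window (one-sided at the ends; window size configurable, raw
speeds by default). Pass 1: speed < 7 µm/s ⇒ trap. Pass 2: consecutive
traps whose end/start positions lie within 2 µm merge (everything between
becomes trap), iterated to a fixed point — iteration makes the result
independent of merge order, and a merged trap can bring a new pair within
range. Trap endpoints are the positions at the first/last frame of the
episode (the literal reading). Equality with a deliberately different
merge-one-pair-at-a-time reference implementation is tested on random
trajectories.

**Run-episode speeds.** An episode's mean speed is path length over time,
counting only steps at or above the trap threshold: confinement events
shorter than the smoothing window (≤ 2 frames at a 1-frame window) are
undetectable by the threshold rule and would otherwise contaminate
episodes with near-zero steps. Pooled run means weight episodes by
running time (estimating the mean instantaneous run speed); unweighted
episode pooling would overweight fast modes, whose runs are chopped into
more episodes because trap encounters scale with speed. The pooled SEM
uses the weighted variance with the Kish effective sample size. Both
choices were validated against ground-truth paths.

**Speeds and MSD.** The whole-trajectory dialect averages one mean speed
per trajectory (unweighted across trajectories, SEM across trajectories;
a point-weighted variant exists but is not the default). MSD is
time-averaged with overlapping windows per trajectory at integer frame
lags (gap frames contribute no pairs), ensemble-averaged with pair-count
weights. Diffusivity is the least-squares MSD slope over a lag window
divided by 4; a log-log slope > 1.5 flags the ballistic regime, in which
case the value is an effective mobility, not a diffusivity.

**Mode tables.** Push/pull/wrapped counts with exact Clopper–Pearson
binomial intervals (run counts in this kind of data are a few hundred, so
the conservative exact construction is appropriate); the CW fraction is
pull + wrapped, and the CW-conditional pull/wrapped split requires at
least one CW run.

**Spreading fronts.** The generator produces
`diameter(t) = d0 + c·max(t − lag, 0)` with `c = 2√(D_eff·g_eff)`,
`D_eff = v²τ/2` converted to mm²/h (v: mean run speed from the free-state
mixture; τ: inverse of the occupancy-weighted rate of stops, reversals and
trap encounters), and `g_eff = division rate × P(motile daughter)`. The
front-speed expression is applied to the diameter directly, absorbing the
radius-to-diameter factor into the effective constants. Defaults: 4 mm
inoculation diameter, 2 h lag. Optional Gaussian noise is followed by a
running maximum (a colony never shrinks). The fit detects the lag by a
slope t-test (5 %) on expanding initial windows, fits a line beyond it,
then refines the breakpoint once from the line's intersection with the
baseline — this recovers the slope of a noiseless lag-plus-line series
exactly, and degrades gracefully on noisy input. Constant series fit with
slope 0; shrinking series warn rather than fail.

**Division/cluster model.** Every cell divides at the division rate
(exponential waiting times, Gillespie); each daughter is independently
motile with the environment's motile-daughter probability; sessile
daughters join the parent's cluster or found one at the division site and
keep dividing. With motile probability 0 and one founder, the expected
cluster size after three doubling times is 8 (branching-process mean),
which the tests check by simulation.

## What the synthetic validation shows — and what it does not

The generator reproduces the *statistical structure* the analysis assumes:
mode-dependent speeds with stationary switching, viscosity-scaled
slowdown, speed-dependent trapping, detection noise and dropouts, and
division-coupled spreading. Passing tests demonstrate that the pipeline
is internally consistent and recovers known parameters under these
conditions (e.g. the full render→link→QC→segment→stats chain recovers the
configured mean run speed of a 500-swimmer agar population within two
Monte-Carlo standard errors; a small residual negative bias of ~0.25 %
from phase-boundary smearing remains and is visible across seeds).

They do not demonstrate correctness on real microscopy: real cells have
correlated speed fluctuations within a run, non-Markovian switching,
finite body size (collisions, out-of-focus blur), drift and illumination
artifacts, and pore-scale geometry that is not a Poisson point process.
Measured speed values (e.g. a 32.1 µm/s bulk mean) enter only as
calibration anchors for the slowdown exponent and as inputs to worked
examples, not as quantities the generator is claimed to reproduce from
first principles.

## Problem sizes

Validation runs use 100–500 swimmers at 10–15 s × 20 fps, 1000 random
short trajectories for the segmentation oracle, 200 instances for the
linking oracle and 500 random walks for diffusivity recovery; these sizes
put Monte-Carlo errors well below the tested tolerances while keeping the
whole suite around ten seconds.
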