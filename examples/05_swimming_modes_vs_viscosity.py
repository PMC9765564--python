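"""Swimming-mode composition as a function of viscous load.

Tabulates push/pull/wrapped run counts from ground-truth labels and shows
how the clockwise (pull + wrapped) runs shift into the wrapped mode as
Ficoll raises the load on the flagellar bundle -- and that the MotAB
knockout cannot wrap at all in plain medium.
"""

import swimtrack as st
from swimtrack.mode_stats import cw_mode_split, tabulate_modes


def run_labels(paths):
    labels = []
    for p in paths:
        prev = None
        for mode, phase in zip(p.mode, p.phase):
            cur = mode if (mode != "stop" and phase == "run") else None
            if cur is not None and cur != prev:
                labels.append(cur)
            prev = cur
    return labels


strains, envs = st.load_default_profiles()

for strain_name in ("wt", "d_motAB"):
    strain = strains[strain_name]
    print(f"\n{strain_name}:")
    for env_name in ("bulk", "ficoll_10", "ficoll_15", "ficoll_20"):
        env = envs[env_name]
        paths = st.simulate_population(120, strain, env, 10.0, dt=0.05, seed=8)
        table = tabulate_modes(run_labels(paths))
        try:
            _, wrapped_cw = cw_mode_split(table)
            wrapped_txt = f"wrapped|CW = {wrapped_cw:5.1%}"
        except ValueError:
            wrapped_txt = "no CW runs"
        print(f"  {env_name:10s} (eta {env.viscosity:4.0f} cP): "
              f"push {table.fractions['push']:5.1%}  "
              f"pull {table.fractions['pull']:5.1%}  "
              f"wrapped {table.fractions['wrapped']:5.1%}  ({wrapped_txt}, "
              f"n={table.n} runs)")

print(
    "\nFor the wild type nearly all clockwise runs are wrapped at 20%"
    "\nFicoll; the MotAB knockout wraps only at intermediate load and"
    "\nnever in plain medium."
)
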