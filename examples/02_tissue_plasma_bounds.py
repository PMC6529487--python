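"""Tissue-to-plasma bounds and organ trajectory classification.

For each bundled organ, prints the theoretical minimum (vascular
confinement) and maximum (interstitial equilibration) tissue-to-plasma
ratios, simulates the organ's time-activity curve at the four scan
times, and classifies the trajectory the way a biodistribution read-out
would: flat at the minimum (brain), at the maximum from the first scan
(lung/liver/spleen), rising in between (muscle group), or beyond the
maximum (kidney residualization, heart blood pool).
"""

from albupet.physiology import load_physiology_table, tp_bounds
from albupet.simulate import SimulationConfig, simulate_organ
from albupet.simulate.plasma import model_from_config
from albupet.tp import build_trajectory

config = SimulationConfig()
physiology = load_physiology_table()
model = model_from_config(config)

print(f"{'organ':<14} {'tp_min':>7} {'tp_max':>7}   t/p at 7/79/120/168 h        class")
for name in config.organ_params:
    organ = physiology[name]
    bounds = tp_bounds(organ)
    ota = simulate_organ(config, organ, model)
    traj = build_trajectory(
        name, ota.times, ota.voi_conc(), ota.plasma_conc, bounds
    )
    ratios = "  ".join(f"{v:.3f}" for v in traj.tp)
    print(f"{name:<14} {bounds.tp_min:7.3f} {bounds.tp_max:7.3f}   {ratios}   {traj.classification}")

# A ratio at tp_min means the tracer never left the organ vasculature; a
# ratio at tp_max means the interstitium reached the plasma concentration.
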