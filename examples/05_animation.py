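"""Render an animation of one simulated TRENSH treatment.

Ingress frames step the injection pressure from 0 to the target in 1-mmHg
increments, coloring every vessel the sclerosant can reach; exit frames then
follow the bolus washing out antegradely after the injection stops.
Writes PNG frames (and a stitched GIF) under ./scratch/animation/.
"""

from trenshsim import (SimulationConfig, attach_nidus,
                       build_extranidal_template, animation_frames,
                       make_pressure_set, sample_architecture)
from trenshsim.viz import render_animation

config = SimulationConfig()
network = attach_nidus(build_extranidal_template(config),
                       sample_architecture(seed=4, config=config))

scenario = make_pressure_set(config, "profound", "normal", None,
                             ("DV2", 30.0))
frames = animation_frames(network, scenario, target_injection=30)
n_ingress = sum(f.phase == "ingress" for f in frames)
print(f"{len(frames)} frames ({n_ingress} ingress + "
      f"{len(frames) - n_ingress} exit)")
peak = max(len(f.filled) for f in frames)
print(f"peak filled vessels: {peak} of {network.nidus.n_vessels} "
      f"({100 * peak / network.nidus.n_vessels:.0f}%)")

paths = render_animation(network, frames, "scratch/animation", stitch=True)
print(f"wrote {len(paths)} files; last: {paths[-1]}")
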