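"""Switched constant-force steering: accelerate binding without biasing it.

Builds the synthetic binding-site system, starts one ligand 18 Å above
the reference arginine, and runs the steering protocol: a 5 kcal/mol/Å
push toward Arg-397 CZ whenever the ligand is inside the extracellular
cone and more than 7 Å away.  Within 7 Å the force is off, so the
binding event itself is spontaneous.
"""

import dataclasses

import numpy as np

from bindsteer import SteeringConfig, build_synthetic_system, run_simulation
from bindsteer.analysis import bias_fraction, detect_binding_events, distance_series

structure, cfg = build_synthetic_system()
cfg = dataclasses.replace(cfg, n_steps=100_000, record_stride=100, seed=1)
result = run_simulation(structure, cfg, SteeringConfig(f0=5.0, cutoff=7.0))

fbt = result.first_binding_times(threshold=7.0, dwell=10)[0]
print(f"first binding time:        {fbt:.1f} ps (distance < 7 Å sustained)")
print(f"bias-active time fraction: {result.bias_fraction:.3f}")
print(f"final binding distance:    {result.distances[-1, 0]:.2f} Å")

ds = distance_series(result.trajectory, "ARG:397:CZ", "LIG1:CA", structure)
events = detect_binding_events(ds, bind_threshold=7.0, unbind_threshold=9.0, dwell=10)
for ev in events:
    print(f"residency: {ev.start:.0f} -> {ev.end:.0f} ps ({ev.residency:.0f} ps)")

# The push is only needed for the initial approach; after that the ligand
# sits in the binding well and the recorded frames are bias-free —
# exactly the behaviour the protocol is designed to give.
assert np.count_nonzero(result.trajectory.flags & (result.distances <= 7.0)) == 0
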