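"""Monte Carlo of the air-electron stream for one beam delivery.

Co-60 photons Compton-scatter in the tilted acrylic phantom; electrons that
escape spiral along the 0.35 T field and deposit dose on the front/end
panels.  Switching the field off makes the directed stream disappear.
"""

from estreamlab import (
    BeamSetup,
    ExperimentCondition,
    PanelSetup,
    PhantomSetup,
    PhysicsConfig,
    SimConfig,
    drx_profile,
    simulate_condition,
)

condition = ExperimentCondition(
    beam=BeamSetup(gantry_angle=0.0, field_size=6.3),
    phantom=PhantomSetup(tilt_angle=20.0),
    panel=PanelSetup("front", distance=10.0),
)

res = simulate_condition(SimConfig(condition, n_photons=1_000_000, seed=7))
print(f"escaped electrons: {res.escaped_count}")
print(f"panel hits (front, end): {res.panel_hit_counts}")
print(f"front-panel D_R1: {drx_profile(res.front_map).values[0]:.3f} cGy")
print(f"end-panel   D_R1: {drx_profile(res.end_map).values[0]:.3f} cGy")

off = simulate_condition(
    SimConfig(condition, n_photons=1_000_000, seed=7,
              physics=PhysicsConfig(b_field=0.0))
)
print(f"end-panel D_R1 without magnetic field: "
      f"{drx_profile(off.end_map).values[0]:.4f} cGy")
print(
    "\nDose units are the package's normalisation (isocenter voxel = 3 Gy);\n"
    "compare values across conditions, not against film readings.  The end\n"
    "panel receives far more than the front, and the hot spot collapses by\n"
    "roughly an order of magnitude without the field."
)
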