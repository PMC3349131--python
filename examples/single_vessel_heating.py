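"""Heat a single straight artery with a focused-ultrasound beam.

Runs the axisymmetric solver for a secondary-branch artery (R = 0.3 mm,
Vm = 8 cm/s) with the beam focused at the vessel centre (half-power width
4 mm, height 30 mm, 15 W/cm^3) for 60 s, and prints the temperature rise at
the vessel wall and 1 mm off-wall, at the focal plane and 10 mm above/below.
Small vessels are poor heat sinks: the wall reaches nearly the off-wall
temperature, so the blood is heated along with the tissue.
"""

import fustherm as ft

scenario = ft.make_scenario("secondary_artery")
grid = ft.Grid.for_cylinder(radial_extent=30e-3, z_extent=40e-3,
                            spacing=0.15e-3)
source = ft.single_vessel_source(focus=(0.0, 0.0, 20e-3))

R = scenario.vessels[0].radius
probes = [(R, 20e-3), (R + 1e-3, 20e-3),        # wall / off-wall, focal plane
          (R, 10e-3), (R + 1e-3, 10e-3),        # 10 mm below (far field)
          (R, 30e-3), (R + 1e-3, 30e-3)]        # 10 mm above (near field)
labels = ["wall@focal", "1mm@focal", "wall@-10mm", "1mm@-10mm",
          "wall@+10mm", "1mm@+10mm"]

result = ft.simulate(scenario, grid, source, duration=60.0,
                     cfg=ft.SolverConfig(dt=0.05, scheme="implicit"),
                     probes=probes, probe_every=100)

final = result.probes.groupby("point_id")["T"].last()
print("Temperature rise after a 60 s insonation (deg C above 37):")
for pid, name in enumerate(labels):
    print(f"  {name:>11s}: {final[pid] - 37:5.1f}")
print(f"  peak anywhere: {result.state.T.max() - 37:5.1f}")
print("Wall and off-wall values are close: a 0.3 mm vessel cannot hold the")
print("lumen at core temperature against focal heating.")
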