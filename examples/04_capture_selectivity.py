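"""Why the array tethers only small vesicles: drag vs adhesion.

Suspension size distributions (measured by light scattering) centre near
133 nm, yet the tethered vesicles measure ~28 nm. The toy capture model
explains this: flow drag on a sphere grows as D^2 while the hydrophobic
anchoring force is size-independent, so only vesicles below a critical
diameter D* = sqrt(F / (c * v)) stay tethered.
"""

import numpy as np

import evnanoarray as ev

rng = np.random.default_rng(0)
suspension = rng.normal(133, 60, 20_000)  # DLS-like suspension, nm
suspension = suspension[suspension > 1]

model = ev.CaptureModel(drag_coefficient=1.0, resistance_force=1600.0,
                        flow_velocity=1.0)  # D* = 40 nm
captured, summary = ev.apply_capture_filter(suspension, model)

print(f"critical diameter D* = {summary['critical_diameter_nm']:.0f} nm")
print(f"suspension mean D: {summary['mean_D_before_nm']:.0f} nm")
print(f"captured mean D:   {summary['mean_D_after_nm']:.1f} nm "
      f"({100 * summary['captured_fraction']:.1f}% of vesicles)")
print()
print("flow-rate scaling (halving v raises D* by sqrt(2)):")
for v in (4.0, 2.0, 1.0, 0.5, 0.25):
    m = ev.CaptureModel(1.0, 1600.0, v)
    _, s = ev.apply_capture_filter(suspension, m)
    print(f"  v = {v:4.2f}: D* = {m.critical_diameter:6.1f} nm, "
          f"captured mean = {s['mean_D_after_nm']:.1f} nm")
print()
print("slower flow captures a larger, more representative size range —")
print("the lever for tuning the platform's size selectivity.")
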