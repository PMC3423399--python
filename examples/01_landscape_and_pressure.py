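"""Build the torsional free-energy landscape and watch pressure reshape it.

The angle psi tracks looping-out of an RNA bulge base: a deep minimum at
the stacked state (psi = 0), a shallower base-triplet-like minimum near
psi = -100 deg, and a barrier on the looping-out path near +70 deg.  A
single dimensionless pressure knob raises the barrier and fills in the
secondary minimum until it disappears.

Run:  python examples/01_landscape_and_pressure.py
"""

import numpy as np

from flipkin import ProfileSpec, make_pmf, profile_features

MINIMA = ((0.0, 3.0), (-100.0, 1.5))   # (position_deg, depth_kT)
BARRIER = 5.0                          # kT, at ambient pressure

print("knob   barrier[kT]  minima (position deg : F kT)")
for knob in (0.0, 0.33, 0.66, 1.0):
    spec = ProfileSpec(minima=MINIMA, barrier_height=BARRIER,
                       pressure_knob=knob)
    profile = make_pmf(spec, grid_step=1.0)
    feats = profile_features(profile)
    desc = ", ".join(f"{p:+7.1f} : {v:.2f}" for p, v in feats.minima)
    print(f"{knob:4.2f}   {spec.effective_barrier():8.2f}     {desc}")

# the profile is an analytic object: energies and forces at any angle
spec = ProfileSpec(minima=MINIMA, barrier_height=BARRIER)
profile = make_pmf(spec, 1.0)
psi = np.array([-100.0, 0.0, 70.0, 120.0])
print("\npsi [deg]     :", "  ".join(f"{x:8.1f}" for x in psi))
print("F(psi) [kT]   :", "  ".join(f"{v:8.3f}" for v in profile.energy(psi)))
print("dF/dpsi [kT/deg]:", " ".join(f"{v:+8.4f}" for v in profile.force(psi)))
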