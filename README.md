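# flipkin

Kinetics of RNA bulge-base flipping on a one-dimensional free-energy
landscape, with umbrella sampling, WHAM, mean first-passage times and
hydration-shell structure analysis — all at desk scale.

## The problem

An unpaired (bulge) base in an RNA duplex can stack inside the helix or
loop out into solvent. A backbone-referenced torsion angle ψ tracks that
motion. At ambient conditions its free-energy profile F(ψ) has a deep
minimum at the stacked state, a shallower minimum attributed to a
transient base-triplet arrangement, and a barrier on the looping-out
path. Raising pressure raises the barrier and fills in the secondary
minimum until it disappears, while simultaneously reorganizing the water
structure around the bulge. This package models that whole story with
controlled synthetic physics:

- **`flipkin.profiles`** — parametric periodic landscapes (sum of
  von-Mises wells plus a barrier hump) with analytic forces, steered by a
  single dimensionless pressure knob in [0, 1];
- **`flipkin.brownian`** — overdamped Langevin dynamics of ψ, a chained
  umbrella-window generator, and a brute-force first-passage ensemble;
- **`flipkin.wham`** — periodic WHAM reconstruction of the potential of
  mean force, plus minima/barrier feature extraction;
- **`flipkin.kinetics`** — the Smoluchowski mean-first-passage-time
  double integral (log-space, overflow-free), boundary selection,
  pressure series and a Kramers cross-check;
- **`flipkin.hydration`** / **`flipkin.geometry`** — radial distribution
  functions, hydration-shell membership and occupancy, OOO angles and the
  tetrahedral order parameter q, on synthetic solvent networks with
  tunable disorder;
- **`flipkin.io`** / **`flipkin.cli`** — plain-text formats (window
  series, PMF tables, minimal GRO/XYZ) and a thin `flipkin` command-line
  tool.

Because every data generator is a pure function of its parameters and a
seed, every number below is exactly reproducible.

## Worked example

Reconstruct a PMF from umbrella sampling and compute the flipping time
(`examples/02_umbrella_to_pmf.py` and `03_flipping_kinetics.py`):

```python
import numpy as np
from flipkin import (ProfileSpec, make_pmf, LangevinModel,
                     generate_umbrella_dataset, bin_windows, wham_solve,
                     pmf_from_probability, FptProblem, mfpt)

truth = make_pmf(ProfileSpec(minima=((0.0, 3.0), (-100.0, 1.5)),
                             barrier_height=5.0))
model = LangevinModel(dt=1.0, record_every=200, seed=0)
windows = generate_umbrella_dataset(truth, np.linspace(-180, 180, 19),
                                    force_constant=0.01, n_samples=5000,
                                    equilibration_discard=500, model=model)
pmf = pmf_from_probability(
    wham_solve(bin_windows(windows, 2.0), windows, tol=1e-8))
```

This converges in 580 WHAM iterations and recovers the generating
landscape with an RMSE of 0.076 kT over all bins below 8 kT — e.g. the
barrier top at +70° comes back as 4.99 kT against a true 4.97 kT.

Kinetics on a 4 kT-barrier double well, three independent ways:

```text
quadrature:  tau =    77012.0   (Smoluchowski double integral)
simulation:  tau =    77750.2 +- 1761.3   (2000 Langevin walkers, z = +0.42)
Kramers:     tau =    38852.4   (harmonic approximation, 4 kT is low for it)
```

The full pressure sweep (`examples/05_full_pipeline.py`, or
`flipkin demo` on the command line) shows the high-pressure signatures —
the flipping time jumps 26× between the two highest pressures and the
secondary basin survives everywhere except at the top knob:

```text
knob   true barrier  recovered   basins   tau
0.00         4.98        5.03      2      2.713e+05
0.33         5.31        5.36      2      3.432e+05
0.66         5.78        5.85      2      4.686e+05
1.00         9.96        9.95      1      1.226e+07
```

Matched hydration frames lose tetrahedral order as the knob rises, with
⟨q⟩ falling from 0.95 to 0.13 while the shell occupancy drops from 9.6
to 5.3 waters.

## Command line

```sh
flipkin simulate-umbrella --out windows/          # synthetic dataset
flipkin wham --windows windows/windows.tsv --out pmf.tsv
flipkin mfpt --pmf pmf.tsv --out mfpt.json
flipkin fpt-sim --n-trials 2000 --out fpt.json    # stochastic oracle
flipkin hydration --frames frames.gro --rc auto --out hyd/
flipkin demo                                      # the whole pipeline
```

Exit codes: 0 success, 2 malformed input, 3 numerical failure.

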