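# Methods

This document records the model, the numerical methods, the default
parameters and the reasoning behind them. Angles are degrees, energies
kT (kT = 1) and the time unit is set by the diffusion constant D
(deg²/time) unless stated otherwise.

## 1. The torsional landscape

The reaction coordinate ψ ∈ [−180°, 180°) is periodic. `ProfileSpec`
composes F(ψ) from von-Mises-shaped terms
a·exp[κ(cos Δ − 1)], Δ = ψ − center (radians), with
κ = (180/(π·width))², so `width` plays the role of a Gaussian σ in
degrees while the function stays exactly periodic and smooth:

- one negative term per specified minimum `(position, depth)`;
- one positive barrier hump whose amplitude is chosen so that the
  **measured** barrier — the profile maximum relative to the primary
  minimum — equals `barrier_height` (`ProfileSpec` therefore requires
  `barrier_height > primary depth`).

Defaults: `well_width = barrier_width = 20°`, barrier at
`primary + 70°`, i.e. on the looping-out path, away from the secondary
minimum at `primary − 100°`.

The pressure knob p ∈ [0, 1] drives two effects:

- barrier growth `B(p) = B₀(1 + 0.2 p + 0.8 p⁸)` — mild up to p ≈ 0.8,
  then sharp, so the top of the range behaves like the high-pressure
  regime where the flipping time jumps by more than an order of
  magnitude;
- secondary-well depth scaling `d(p) = d₀(1 − p)` — the base-triplet-like
  minimum becomes shallower and disappears exactly at p = 1.

`make_pmf` tabulates the profile on a uniform grid (grid step must
divide 360), shifts the minimum to zero, and attaches analytic
energy/force callables plus the raw von-Mises terms so integrators can
use a compiled kernel.

## 2. Overdamped Langevin dynamics

`simulate_langevin` integrates dψ = −(D/kT) F′(ψ) dt + √(2D dt) η by
Euler–Maruyama. Forces are always evaluated on the wrapped angle;
optionally the trajectory is returned unwrapped (for mean-squared
displacement checks). Two guards warn about discretisation trouble:
a drift exceeding 5°/step anywhere on the profile, and a harmonic bias
with D·dt·k/kT > 1 (the overdamped stability bound).

When `numba` is importable and the profile carries analytic von-Mises
terms, single-walker runs use a compiled kernel that consumes the same
pre-drawn noise stream as the numpy path; both paths agree to ~1e-14
per step and the kernel is roughly 200× faster. `numba` is deliberately
not a hard dependency.

`generate_umbrella_dataset` chains windows: window i is restrained by
½k(ψ−ψᵢ)² and starts from the final state of window i−1 (window 0 at
its own center), mimicking a sequential pulling protocol. Each window
draws from an independent generator seeded by `(seed, i)`, so the whole
dataset is a pure function of its inputs. A spacing larger than
3·√(kT/k) triggers an overlap warning.

`simulate_fpt` runs walker ensembles on a bounded interval with a
reflecting wall (one fold, then clamp — valid for the small per-step
displacements the drift guard enforces) and an absorbing target;
orientation with the absorbing boundary below the reflecting one is
handled by mirroring the coordinate. Walkers alive after `max_steps`
are reported as censored rather than silently dropped.

## 3. WHAM

`wham_solve` iterates the standard self-consistent equations on a shared
periodic binning,

    P_j ∝ Σᵢ n_ij / Σᵢ Nᵢ exp[−(w_i(ψ_j) − fᵢ)/kT],
    exp(−fᵢ/kT) = Σ_j P_j exp(−w_i(ψ_j)/kT) Δψ,

with the bias evaluated at bin centers on the minimum-image angular
difference (so windows at ±180° wrap correctly; a non-periodic mode
exists for truncated intervals). The gauge is f₁ = 0; convergence is
maxᵢ|Δfᵢ| < tol. Empty bins are never imputed: they stay masked through
`pmf_from_probability` (F = −kT ln P, min-shifted), and a single empty
bin flanked by occupied ones triggers an insufficient-overlap warning.
With one unbiased window the equations collapse to the raw histogram
estimate exactly — a degeneracy the tests check to 1e-10.

`profile_features` finds local minima by a discrete three-point rule
(plateaus report their leftmost bin; masked profiles are analysed on the
largest contiguous segment) and reports inter-minimum barriers on each
periodic arc, measured from the shallower of the two minima. An
optional prominence filter iteratively drops minima whose prominence is
below a threshold — never the deepest one — which suppresses the
statistical wiggles of reconstructed PMFs.

## 4. Mean first-passage time

For diffusion on F(ψ) with reflecting boundary a and absorbing boundary
b, the MFPT from x₀ is

    τ = (1/D) ∫_{x₀}^{b} dy e^{F(y)/kT} ∫_{a}^{y} dz e^{−F(z)/kT}.

`mfpt` evaluates both integrals in log space (cumulative log-sum-exp
over trapezoid segments), so barriers of tens of kT cannot overflow;
a 60 kT barrier yields τ ~ 1e24 with no special handling. The grid is
refined by doubling until τ changes by less than `rtol` (default 1e-3),
and the last relative change is reported as the discretisation-error
estimate. The interval is treated as bounded and non-periodic — the
reflecting wall breaks the periodicity of ψ.

`select_boundaries` picks x₀ as the deepest PMF minimum, b as the
user's looped-out target, and the reflecting wall as the first grid
point on the far side of x₀ where F has risen `reflect_offset` (default
3 kT) above F(x₀), falling back to the domain edge. `kramers_estimate`
provides the harmonic high-barrier approximation
k = (D/2πkT)·√(F″_well·|F″_barrier|)·e^{−ΔF/kT} as an independent
sanity check; it flags βΔF < 2 as outside its validity.

## 5. Hydration-shell analysis

Solvent is represented by oxygen positions in an orthorhombic periodic
box (minimum-image convention throughout). `rdf` normalises by the
ideal-gas shell count, lightly smooths (3-bin moving average) before
locating the first maximum and the following first minimum — the
conventional shell cutoff r_c. `shell_membership` selects solvent
within r_c of any solute atom; membership only restricts which central
molecules enter an average, while neighbor searches always run over all
solvent, since a shell-edge molecule's nearest neighbors may lie just
outside the shell.

The tetrahedral order parameter is
q = 1 − (3/8) Σ_{i<j} (cos θ_ikj + 1/3)² over the six pairs among the
four nearest neighbors: exactly 1 for a perfect tetrahedron, 0.5 for
square planar, −3 for four collinear neighbors, and mean 0 for
isotropic directions. `shell_occupancy` histograms N_w over frames.

`geometry` supplies the synthetic stand-ins for MD snapshots:

- `lattice+noise`: a diamond-cubic network (lattice constant
  a₀ = 4·0.28/√3 nm, so nearest neighbors sit at the water-like
  0.28 nm and subtend 109.47° exactly) plus isotropic Gaussian jitter
  of standard deviation bond·σ_rad, the arc length a neighbor direction
  swings through at angular scale σ. Configurations implying
  closer-than-hard-sphere (0.15 nm) nominal bonds are rejected.
- `ideal_gas`: uniform placement, with a Poisson-drawn count when a
  density is given — making shell occupancy exactly Poisson.
- `fixture`: pass-through for hand-built coordinates.

## 6. Default study conditions and why

| parameter | default | reason |
|---|---|---|
| windows | 19 over [−180°, 180°] | 20° spacing = 2σ of the bias distribution |
| force constant k | 0.01 kT/deg² | bias σ = √(kT/k) = 10°: neighbor histograms overlap at ~2σ |
| dt | 1.0 | per-step noise 1.4° at D = 1; max drift ≪ 5°/step |
| record_every | 200 | ≈ 2× the window relaxation time kT/(Dk) = 100: samples nearly independent |
| samples/window | 5000 after 500 discarded | recovery RMSE ≈ 0.08 kT at these settings |
| WHAM bin | 2° | resolves 10°-wide features; ≥ 100 counts/bin in wells |
| WHAM tol | 1e-8 kT | far below statistical error; converges in O(500) iterations |
| flip target | +120° | past the barrier (+70°), before the next basin |
| reflect offset | 3 kT | wall well above the starting basin, left of it |

These are study conditions, not tuning knobs: they were frozen from the
relaxation-time and overlap arguments above plus convergence
diagnostics on the generator itself, before the validation thresholds
were evaluated.

## 7. Known limitations

- Euler–Maruyama has O(dt) weak bias; at dt = 1 the first-passage means
  sit ~1% from the quadrature values, visible only because the
  quadrature is much tighter than that.
- WHAM recovery error at the default protocol (~0.08 kT RMSE) is
  dominated by statistical accumulation of the window constants across
  the barrier, not by bin discretisation; stiffer or softer biases do
  not improve it at fixed total samples.
- The Kramers check is only meaningful for βΔF ≳ 5 and harmonic-ish
  extrema; at a 4 kT barrier it is off by ~2× (and says so via its
  `low_barrier` flag at βΔF < 2).
- `rdf`'s first-minimum detector assumes a structured first shell; it
  returns None on featureless (ideal-gas) curves by design.
- The prominence filter can keep a flat-arc plateau minimum on noiseless
  single-well profiles; barrier heights for such profiles are better
  read from the profile extrema directly.
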