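# Methods

## Model

`isosim` simulates MR image acquisition by isochromat summation. The
phantom is a voxel grid with, per tissue, a fuzzy occupancy volume in
[0, 1] and a property row (ρ, T1, T2, δB). Every (voxel, tissue with
nonzero fraction) pair spawns an isochromat at the voxel center (or on
a regular s³ sub-grid for `n_per_voxel = s³ > 1`) with equilibrium
magnetization m₀ = fraction·ρ/n_per_voxel, so voxel magnetization is
conserved under subdivision. Partial-volume contrast is therefore not a
post-hoc mixing rule: boundary voxels physically contain isochromats of
several tissues.

The state of each isochromat is a 3-vector updated by three exact
operators:

* **Free evolution** for Δt at relative frequency ν = γ(B − B₀):
  z-rotation by ν·Δt (sign convention: +x rotates onto −y for positive
  ν), then diagonal T2/T1 relaxation, then the recovery term
  M₀(1 − e^(−Δt/T1)) on z — in that operator order. The update is the
  exact solution for piecewise-constant fields, so one call spans an
  entire event regardless of duration; there is no time-step error.
* **Hard RF pulse**: Ry(β)·Rx(θ)·Ry(−β) with β = atan((Bt−Bi)/B₁) and
  θ = γτ√((Bt−Bi)²+B₁²). Relaxation is not applied during the pulse
  (τ defaults to 10 µs, orders of magnitude below tissue T2). Shaped
  pulses are trains of rectangular segments applied in order.
* **Acquisition**: the sample is ΣMx + i·ΣMy over all isochromats;
  sample recording alternates with one-dwell evolution under the
  readout gradient, sample 0 at the event start.

The simulation frame rotates at the demodulation frequency γB₀;
acquired samples are rotating-frame quantities and no separate
demodulation step exists. RF pulses are tuned to the isocenter field
(Bt = B₀); there is no slice selection — 3D matrices use a second
phase-encode loop instead.

## Spin-echo timeline and k-space conventions

Each repetition (one phase-encode line) is:

    90°x | encode interval (PE gradient + read prephaser), TE/4
         | free evolution to TE/2
    180°x | free evolution to the readout start
    readout (N samples, echo-center sample N/2 at exactly TE)
         | free evolution to TR

Durations sum to TR exactly. The 180° pulse negates accumulated phase,
so the *positive* prephaser of half the readout area places sample 0 at
kx = −(N/2)Δk; each dwell advances kx by Δk = 1/FOV, giving the
half-open symmetric grid {−N/2, …, N/2−1}Δk with DC at index N/2.
Phase-encode amplitudes follow the same ladder in ky (increasing line
index = increasing ky). Wrap-around aliasing of off-FOV objects then
emerges from the grid arithmetic itself, and a static tissue offset δB
displaces the image by δB/(G_read·Δx) voxels along the readout axis —
both are validated end to end in the acceptance tests.

Reconstruction is the centered inverse DFT (`ifftshift → ifftn →
fftshift`, backward normalization, so Σ|k|² = N·Σ|image|²) with one
extra half-sample linear phase per axis. The phase aligns the DFT
output grid with the phantom's grid-centered voxel coordinates
(j − (N−1)/2)·Δx, so a point object at voxel j reconstructs at index j
rather than j + ½. Axes are reordered to (x, y[, z]) to match the
phantom.

Magnetization evolves continuously across repetitions. One unrecorded
preparation repetition is run first (configurable): after any 90° the
longitudinal component is exactly the previous transverse one, so
whenever transverse magnetization has decayed within TR — true for all
shipped scenarios, where TR ≫ T2 — a single preparation repetition
already lands on the TR-periodic steady state.

## Relation to the analytic signal equation

The signal equation S = ρ(1 − e^(−TR/T1))e^(−TE/T2) neglects that the
180° pulse at TE/2 inverts the partially recovered longitudinal
magnetization. The exact periodic steady state of the simulated
sequence is

    Mz⁻ = M₀ · (1 − (2 − e^(−TE/2T1)) · e^(−(TR−TE/2)/T1)),

which differs from the closed form by ≈ e^(−TR/T1)·TE/T1 (relative).
The engine reproduces the exact expression; the oracle comparison is
therefore meaningful only in the equation's own validity regime
TE ≪ T1. The validation grid spans TE ∈ [T2/2, 2T2] and
TR ∈ [T1/2, 3T1], so the homogeneous validation phantom uses a
tendon-like short-T2 tissue (T1 = 600 ms, T2 = 12 ms, T2/T1 = 0.02),
for which the analysis above bounds the discrepancy at ≈ 3 % after one
global scale — the measured maximum. The global scale between engine
and oracle is fitted minimax (geometric mean of the extreme
engine/oracle ratios), matching the max-relative-deviation metric.

With `n_per_voxel = 1` and an exact 180° hard pulse, static intravoxel
dephasing refocuses exactly at the echo; higher `n_per_voxel` exposes
intravoxel-dephasing studies (e.g. with a ΔB₀ map) at cubically growing
cost.

## Deterministic parallel decomposition

Isochromats are divided evenly among managers and each manager's share
among its workers (contiguous spans, sizes differing by ≤ 1, no
slice-boundary alignment; empty spans allowed). The tree is executed
logically — worker chunks run one after another — because on a single
CPU the numpy-vectorized chunks already saturate the machine and a
process pool would only add transport cost; only the decomposition and
reduction *order* carry numerical meaning.

Floating-point addition is not associative, and the even-split
partitions for different worker counts are not mutually nested, so no
summation tree over per-worker partial k-spaces can be invariant to the
worker count. The engine therefore reduces at per-isochromat grain:
workers return their isochromats' signal rows, `reduce_signals`
concatenates them manager-major/worker-major (restoring ascending
isochromat order bit for bit for every partition) and applies one
canonical sum over the isochromat axis. k-space is consequently
bit-identical for any manager/worker configuration, which the tests
assert with exact array equality. For the same reason the per-isochromat
gradient term is computed with elementwise ufunc arithmetic rather than
a BLAS mat-vec, whose kernel choice (and hence rounding) depends on
array shape. Memory for the reduction is one n_isochromats × n_samples
complex block per line.

## Synthetic phantoms

The generators emulate the structure of fuzzy voxel-based anatomical
phantoms (one occupancy volume per tissue class, partial-volume
boundaries) without requiring any external data:

* **sphere** — uniform tissue, boundary occupancy from s³ sub-voxel
  sampling (strict interior test, so radius 0 is empty);
* **layered brain-like** — concentric bands (skin, skull, fat, CSF,
  grey, white, …, up to 8 template layers with representative 1.5 T
  properties) around a seeded, harmonically wobbled outline; band edges
  are smoothed over ≈ 1 voxel so inter-layer voxels mix the adjacent
  tissues and fractions telescope to exactly 1 inside the head.

These phantoms reproduce the partial-volume and geometric structure of
real fuzzy anatomies but not their anatomical detail, coil or noise
characteristics; passing tests demonstrate correctness of the
acquisition physics and encoding, not realism of any particular
anatomy. Seeded complex Gaussian k-space noise is available but off by
default, since the acquisition model itself is noiseless.

## Defaults and problem sizes

* γ = 2.67522128×10⁸ rad s⁻¹ T⁻¹ (hydrogen), B₀ = 1.5 T — configuration,
  not physics assumptions.
* dwell = 20 µs (50 kHz readout bandwidth): keeps the readout window
  ≪ T2 so the echo envelope is flat across it; the chemical-shift
  scenario lowers bandwidth (dwell 100 µs) to realize a 3-voxel shift
  with δB ≪ B₁.
* RF duration 10 µs; encode interval TE/4.
* Validation scenarios use 16³ (full 3D acquisition) and 32²
  single-slice matrices with ~10²–10³ isochromats — sizes chosen so the
  entire validation battery completes in seconds while leaving every
  measured property (contrast, encoding, artifacts, determinism)
  resolution-independent.

## Known limitations

* No slice-selective excitation, gradient ramps/slew limits, spoiling,
  multi-echo trains or EPI; sequences are hard-pulse spin echoes built
  by `build_spin_echo` (arbitrary event lists can be run directly).
* No diffusion, flow, or magnetization transfer; T2′ effects appear
  only through an explicit ΔB₀ map with `n_per_voxel > 1`.
* The logical worker tree does not execute in parallel processes; it
  exists for deterministic decomposition semantics.
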