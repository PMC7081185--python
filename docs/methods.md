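# Methods

This note records the scientific and numerical choices behind `vsimri`:
what each stage assumes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Susceptibility physics and unit conventions

Two frequency scales appear and must not be conflated.

**Characteristic frequency of the index equations.** The VSI equation
`VSI = 0.424·(D/Δω_c)^(1/2)·(ΔR2*/ΔR2)^(3/2)` uses
`Δω_c = γ·Δχ·B0` with the susceptibility difference quoted as a CGS
number (4.5×10⁻⁷ for the SPION dose used here), giving
Δω_c ≈ 842.6 rad/s at 7 T. The 0.424 prefactor is calibrated to this
convention, and `PhysicsConfig.chi_convention` controls it:
`as_given` (default) uses the stored value verbatim; `si_from_cgs`
multiplies by 4π.

**The perturber field itself.** The physical dipole field of a voxel
carrying a CGS susceptibility difference Δχ is
`ΔB = Δχ·B0·V·(3cos²θ−1)/r³` — equivalently the SI expression with
`Δχ_SI = 4π·Δχ_CGS`. The field computation always uses this physical
scale, regardless of `chi_convention`. The two conventions are not
interchangeable: a field built from the CGS number dropped into the SI
kernel would be 4π too weak, capping the static gradient-echo rate change
at ~5.6 s⁻¹ for 2% blood volume — an order of magnitude below what the
spin-echo data show — whereas the physical field yields the
self-consistent triplet ΔR2* ≈ 65–70 s⁻¹, ΔR2(3 um) ≈ 16–19 s⁻¹ and
VSI ≈ true radius.

## Finite-perturber Monte Carlo simulator

**Substrate.** Microvessels are randomly oriented, randomly positioned
cylinders of one radius in a periodic cubic grid (default 1 um voxels).
Each cylinder is a chord segment of length √3·L rasterized as a dense
union of digital balls along its axis (sample spacing 0.5 voxel,
periodic wrap); a voxel is occupied when its centre lies within the
radius of some axis sample. Cylinders are added until the occupancy
fraction first reaches the target blood volume fraction (Bvf); the last
cylinder is trimmed sample-by-sample so the achieved Bvf lands within
±10% of the target even when one full crossing would overshoot it (large
radius on a small grid). Achieved Bvf is the exact occupied-voxel
fraction. The ground-truth areal density reported with each substrate is
the stereological L_V/2 (total axis length per volume, halved).

**Field map.** The total frequency shift is the superposition of the
single-voxel dipole fields of all occupied voxels, computed as a
circular convolution of the occupancy grid with the *real-space*
periodized dipole kernel via FFT. We deliberately do not multiply by the
continuous k-space dipole factor (1/3 − kz²/k²): sampled on the DFT grid
that kernel rings strongly for voxel-scale sources (the single-voxel
field acquires sign errors on-axis), while the real-space kernel makes
every perturber's field exactly dipolar — which is what
"sum of the field shifts of all perturbers" means. The kernel's k=0 term
is removed, so the mean field over the periodic box is zero; only field
differences drive dephasing. B0 lies along the grid z-axis; cubic voxels
are required.

**Random walk.** Walkers start uniformly in the extravascular space
(vessels are impermeable; a step landing inside a vessel is rejected and
the walker waits one interval). Default step: fixed length √(6·D·Δt) in
a uniformly random direction, which realizes the nominal diffusivity
D = 800 um²/s in 3-D; `step_mode` also offers `fixed_1d` (√(2DΔt), the
1-D diffusion-length convention — it realizes D/3 and visibly inflates
derived VSI) and a 6-neighbour `lattice` mode. Phase accrues as
Δω(position)·Δt with nearest-voxel lookup; the spin echo inverts the
accumulated phase at TE/2. Δt = 1 ms by default; the 3 ms gradient echo
therefore takes 3 steps, and a `substeps` factor is available because
phase-accrual discretization at 3 steps is coarse (default 1).
Signals are `S = |⟨e^{iφ}⟩|`, rates `ΔR2(*) = −ln S(TE)/TE` at
TE = 8 ms (spin echo) and 3 ms (gradient echo).

**Seeding.** Every condition derives child seeds as
`SeedSequence((master, condition index, repetition))`: repetitions are
independent, conditions do not share streams, identical seeds give
bit-identical results.

**Reduced problem sizes.** The full-scale protocol (400³ grid, one walker
per voxel = 64,000,000) is supported but not exercised by the tests. The
default testing profile uses 2×10⁵ walkers and 3–5 repetitions, with the
reference condition on a 128³ grid. For the radius sweep the grid grows
with radius (128³ up to 4 um, 192³ to 6 um, 256³ above): a substrate must
hold several independently oriented cylinders for the orientation average
to converge — a single orientation contributes a ±45% spread to ΔR2*
(∝ sin²θ) — and the scaled grids keep the cylinder count per substrate
comparable to the full-scale study (~4–6 at Bvf 2%).

**Static-dephasing oracle.** For dilute randomly oriented cylinders with
no diffusion, the gradient-echo signal has the closed form
`ln s(t) = −ζ·⟨g(C(θ)t)⟩_θ`, `g(x) = x∫₀ˣ(1−J0(v))/v² dv`,
`C(θ) = ½γΔχ_SI·B0·sin²θ`, long-time rate `ζγΔχ_SI·B0/3`. It is
evaluated by quadrature only and serves as an independent check of the
simulator (D→0, radius 10 um agrees within ~5%; the test tolerance is
15%, dominated by the orientation-sampling error of ~70 draws).

## Relaxometry and microvascular maps

Fits of `S = S0·exp(−rate·x)` run as damped Gauss–Newton iterations
vectorized over voxels, initialized by log-linear regression; b-values in
s·mm⁻² give ADC (reported in um²/s, one documented ×10⁶ conversion), TEs
in ms give R2/R2* (reported in s⁻¹). Voxels whose maximum series
intensity falls below 5% of the series' 99th-percentile intensity are
background and invalid. Non-convergent voxels are marked invalid, not
raised.

ΔR2 and ΔR2* subtract pre- from post-contrast fitted rates
(`fitted_train`) or use the first echo directly (`first_echo`). The
echo-train ΔR2 is multiplied by the calibration factor 4.375 (an opaque,
protocol-specific constant; provenance records the factor actually
applied, and first-echo maps record 1.0). Negative ΔR voxels stay in the
raw map but are excluded from VSI/Q/MVD.

**Noise floor.** Post-contrast R2* in edema-like tissue reaches
~200 s⁻¹, so late gradient echoes sink into the Rician background
(mean σ√(π/2)). The rate fitters accept a per-voxel intensity floor;
the pipeline estimates σ from the background magnitude and excludes
echoes below 3σ (voxels left with <3 echoes become invalid). This is
standard threshold fitting, not a Rician likelihood correction; noiseless
fits use plain least squares. Without the floor, fitted lesion ΔR2* is
biased low by tens of percent and the VSI contrast between lesion and
normal tissue is compressed.

At SNR 40 with the 6-b-value protocol, the per-voxel ADC precision is
bounded by the Cramér–Rao limit at ~3.3% relative SD; the least-squares
fits sit within ~30% of that bound. Sub-percent voxelwise accuracy is not
attainable at these settings and is not claimed.

## Vessel morphometry

Vasculature is segmented as `intensity > threshold`, the threshold
sitting at the noise/signal boundary and shared across longitudinal
volumes of one subject. Vessel caliber is Hildebrand–Rüegsegger local
thickness: the diameter of the largest sphere fully inside the structure
covering each voxel, computed as a Euclidean distance transform followed
by sphere painting in decreasing-radius order.

Digital-ball convention: a sphere anchored at voxel c covers voxel
centres within EDT(c) of c (centre-to-centre reach), while its physical
radius is EDT(c) − 0.5, because the continuous tissue boundary lies half
a voxel inside the nearest background centre. Consequences: an isolated
voxel reads 1 voxel across; a digital cylinder of radius r reads
≈ 2r − 0.8, i.e. the radius-5 benchmark tube reads 9.2 voxels (within
the ±1 voxel acceptance of the true 10). An exhaustive maximal-sphere
oracle with the same convention reproduces the fast implementation
exactly on all test masks. "Main branch" selection is caller-supplied
(explicit branch masks); a largest-connected-component helper exists as
a convenience. Anisotropic voxels are rejected; no denoising is applied
before thresholding (an optional Gaussian blur exists purely as
plumbing).

## Lesion statistics

A region is ischemic edema when its mean ADC is below 650 um²/s and
normal above; exact equality classifies as normal (the threshold rule
leaves equality undefined; ties are measure-zero). ROI summaries use only
valid voxels and retain the raw value vectors for histograms and tests.
Student's t-tests (two-sided throughout; pooled variance when unpaired)
are assembled from means and variances directly, with the t CDF as the
only special function, and are cross-checked against an independent
reference implementation. Zero-variance cases: equal means give t = 0,
p = 1; unequal means are flagged degenerate with p = 0. Cutoff
proportions use strict inequality (VSI > 10 um, MVD > 200 mm⁻²).
Longitudinal macrovascular pooling takes, per animal, the maximum venous
and minimum arterial diameter over early reperfusion days and the day-7
value for the late phase.

## Synthetic phantoms

The brain phantom is two half-ellipsoid hemispheres (96×96×48 voxels at
0.3 mm, ~1 voxel midline gap) with a cortical shell and a spherical
subcortical lesion in one hemisphere. Tissue values are piecewise
constant: ADC 750 vs 500 um²/s, VSI 4 vs 12 um, Q 1.07 vs 0.6 s^(−1/3)
(normal vs lesion) — magnitudes chosen to straddle the working cutoffs
650 um²/s, 10 um and 200 mm⁻² in the directions seen in subcortical
ischemic edema. Ground-truth ΔR2/ΔR2* maps are obtained by inverting the
VSI and Q equations (ρ = rate ratio from VSI, ΔR2* = (ρQ)³), so the
mapping stage has an exact target and the truth satisfies
MVD = Q³/(4.725·D) identically; inconsistent specs (VSI below the
ratio-1 floor) are rejected. The rendered post-contrast spin-echo rate
grows by ΔR2/4.375, emulating the echo-train underestimate that the
4.375 factor corrects. Baselines R2 = 15 s⁻¹ and R2* = 30 s⁻¹; S0 = 1000
inside the brain, 0 outside; Rician noise at SNR = S0/σ (default 40).
Acquisition axes: b = 100–1000 s·mm⁻² (6 values), spin-echo train
8–160 ms every 8 ms, gradient-echo train 3–59 ms every 4 ms.

What the phantom does *not* emulate: anatomically realistic geometry,
partial-volume and susceptibility boundary artifacts, motion, coil
profiles, multi-compartment diffusion, or vascular-tree branching.
Passing tests therefore demonstrate correctness of the computation chain
under the stated signal model, not robustness to every in-vivo
confound. In particular, the in-vivo medians (VSI 4.06 um,
Q 1.07 s^(−1/3), MVD 337.4 mm⁻²), the animal-level p-values (0.0051,
0.0096) and the microscopy-atlas comparison depend on undeposited animal
data and external atlases and are not reproducible here; the phantom
direction tests (higher VSI, lower Q/MVD in edema, p < 0.05) stand in
for them.

Tubular phantoms rasterize capsule segments of known radius on a
non-periodic grid, returning both a noisy intensity volume (for
threshold tests) and the exact mask (for thickness tests), with
per-segment truth bookkeeping.

## Known limitations

* The simulator's 3-step gradient echo (Δt = 1 ms, TE = 3 ms) carries
  phase-discretization error for walkers crossing steep field gradients;
  `substeps` refines it at linear cost.
* Orientation statistics dominate the Monte Carlo spread at large radius;
  condition means at radius ≥ 8 um carry ~10% standard errors at the
  default repetition counts.
* The intravascular space contributes no signal (walkers are excluded),
  consistent with an impermeable-vessel model at high intravascular
  relaxivity; partial-volume intravascular signal is not modelled.
* `local_thickness` is O(Σ sphere volumes); it is intended for branch
  masks and test-sized volumes, not whole 512³ angiograms.
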