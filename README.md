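# vsimri — dual-contrast vessel size imaging

`vsimri` is an analysis package for **ΔR2–ΔR2\* vessel size imaging (VSI)**:
mapping microvessel caliber and density in the brain from the change in
transverse relaxation rates induced by an intravascular susceptibility
contrast agent (SPION), together with the supporting pieces of a
dual-contrast stroke-imaging workflow — diffusion (ADC) mapping of
ischemic edema, angiographic vessel-diameter morphometry, and
edema-versus-normal lesion statistics. It is aimed at preclinical MR
physicists and image analysts who want the full computation chain — from
Monte Carlo validation of the physics to voxel-wise maps and ROI
statistics — reproducible on synthetic ground-truth data.

## The model

An intravascular agent with susceptibility difference Δχ in a field B0
makes each vessel a magnetic perturber. Spin-echo and gradient-echo
sequences respond differently to the resulting microscopic field
gradients: the gradient-echo rate change ΔR2\* is nearly independent of
vessel radius (static dephasing), while the spin-echo change ΔR2 falls
with radius (diffusional averaging), so the pair encodes vessel geometry:

    VSI [um]      = 0.424 · (D / (γ·Δχ·B0))^(1/2) · (ΔR2*/ΔR2)^(3/2)
    Q   [s^-1/3]  = ΔR2 / (ΔR2*)^(2/3)
    MVD [mm^-2]   ≈ Q³ / (4.725·D)

with D the water diffusion coefficient (800 um²/s), γ the proton
gyromagnetic ratio, B0 = 7 T and Δχ = 4.5×10⁻⁷ (CGS value, used verbatim
in the characteristic frequency γΔχB0 ≈ 842.6 rad/s).

The package implements:

* **`fpm_engine`** (`substrate`, `fieldshift`, `montecarlo`, `sweep`,
  `static_dephasing`) — a finite-perturber Monte Carlo simulator: random
  cylinder substrates, per-voxel dipole-superposition field maps
  (FFT-accelerated, periodic), random-walk proton phase accrual with
  impermeable vessels, ΔR2/ΔR2\* = −ln S(TE)/TE, plus an analytic
  static-dephasing closed form used as an independent oracle.
* **`relaxometry`** — vectorized mono-exponential fitting (ADC, R2, R2\*),
  pre/post-contrast ΔR2/ΔR2\* maps (echo-train fits carry the 4.375
  calibration factor; first-echo mode available), and VSI/Q/MVD maps.
* **`morphometry`** — threshold segmentation of angiographic volumes and
  maximal-inscribed-sphere local thickness for vessel diameters.
* **`lesions`** — ADC-threshold tissue classification (edema < 650 um²/s),
  ROI summaries, cutoff proportions (VSI > 10 um, MVD > 200 mm⁻²),
  first-principles Student's t-tests, double-box tables, and longitudinal
  macrovascular pooling.
* **`phantom`** — seeded ground-truth generators: a two-hemisphere brain
  phantom with a subcortical edema lesion whose rate maps are constructed
  by *inverting* the VSI/Q equations, and tubular vessel phantoms of known
  radius. Rician noise throughout.
* **`io` / `config` / `pipeline` / `cli`** — NIfTI+JSON I/O, YAML config,
  an end-to-end orchestrator with a hashed manifest, and the `vsimri`
  command-line tool (`simulate`, `make-phantom`, `fit-adc`, `fit-rate`,
  `delta-map`, `vsi-maps`, `vessel-diameter`, `lesion-stats`, `run-all`).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`. For example:

```sh
python analysis/01_simulate_sweep.py --seed 0
```

prints (abridged):

```
reference condition (r=3 um, Bvf 2%): dR2 = 19.1 +- 2.7 s^-1, dR2* = 72.2 +- 11.8 s^-1
Bvf 2%: dR2 falls 24.2 -> 6.4 s^-1 across radii; dR2* flat to +-19%; VSI 1.9 -> 13.0 um tracks radius
Bvf 4%: dR2 falls 44.3 -> 11.9 s^-1 across radii; dR2* flat to +-7%; VSI 2.0 -> 13.2 um tracks radius
Bvf 6%: dR2 falls 63.2 -> 20.2 s^-1 across radii; dR2* flat to +-12%; VSI 1.9 -> 13.5 um tracks radius
```

— the spin-echo rate change at 2% blood volume and small radii sits near
20 s⁻¹, the gradient-echo change is flat in radius and scales with blood
volume, and the VSI derived from the simulated rates recovers the true
cylinder radius. `analysis/02_phantom_mapping.py` then runs the voxel-wise
pipeline on the SNR-40 brain phantom:

```
contra_subcortex ADC    749 um^2/s (normal)  VSI  4.30 um (> 10 um: 0.2%)  Q 1.043  MVD   324 mm^-2 (> 200: 78.2%)
lesion           ADC    500 um^2/s (edema )  VSI 12.87 um (> 10 um: 71.7%)  Q 0.595  MVD    62 mm^-2 (> 200: 0.8%)
lesion vs contralateral subcortex, vsi: t = 248.2, p = 0.00e+00
```

— the lesion classifies as ischemic edema and shows the expected
microvascular signature: enlarged vessels (heavier VSI tail above 10 um)
at reduced density (lower Q, smaller MVD fraction above 200 mm⁻²).
`analysis/03_vessel_morphometry.py` and `analysis/04_lesion_statistics.py`
cover diameter morphometry (radius-5 tube → 9.2 ± 0.0 voxels across) and
the edema/normal statistics with macrovascular pooling.

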