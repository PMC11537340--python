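# Methods

## Scope

`dsdge` models the direct-water-saturation dynamic glucose enhanced (DS-DGE)
experiment at 3 T: low-B1 pulsed saturation Z-spectra of glucose-bearing
brain-tissue compartments, single-Lorentzian linewidth (LW) extraction, and
the dynamic ΔLW / AUC mapping pipeline, plus a digital phantom that exercises
everything end to end. Scanner readout physics (EPI, k-space), semisolid MT
and rNOE pools, motion correction, and tracer-kinetic (DCE/DSC) modelling are
out of scope; motion correction is treated as an external pre-processing hook
whose execution is only recorded.

## Bloch-McConnell core

Each proton pool contributes (Mx, My, Mz) to a coupled linear system; the
affine generator stacks per-pool precession (Δω relative to the RF carrier,
ppm × 42.577 MHz/T × B₀), relaxation (R₁, R₂), RF nutation (ω₁ = γB₁) and
two-site exchange with water under detailed balance (water→pool rate equals
the pool→water rate times the pool's proton fraction). Propagation through a
shaped pulse is piecewise-constant: the envelope is sampled (32 samples per
pulse by default; doubling changes Z by < 1e-5) and the homogeneous
(3n+1)-dimensional generator exponentiated per sample. A fixed-step RK4
integrator at 10× finer steps serves as the independent oracle in the tests
(< 1e-4 agreement).

Glucose contributes four hydroxyl pools (0.66, 1.28, 2.08, 2.88 ppm) with
proton multiplicities 1 : 3 : 0.36 : 0.64 per glucose molecule (the anomeric
OH split 36:64 over the α/β anomers) relative to 111 000 mM water protons,
T₁ = 1.20 s, T₂ = 0.100 s, and exchange rates 2900/6500/5200/14 300 s⁻¹ at
pH 7.2 or 1500/3100/2500/6000 s⁻¹ in acidic tumor EES.

## Saturation models and the sideband question

The saturation train is 10 consecutive 50 ms sinc-Gauss pulses at
B1peak = 0.5 µT. The exact envelope of the scanner pulse is not a published
quantity; the shipped default is a Gaussian-apodized sinc with time-bandwidth
product 2.6 and σ = T/4, peak-normalized — a textbook sinc-Gauss whose
amplitude average is 0.376 × B1peak. Both parameters are configuration fields.

Propagating a *single isochromat* through this literal train produces
coherent nutation sidebands at harmonics of the 20 Hz pulse repetition rate
(and, when cycled to the TR steady state, a dense 1/TR comb). For long-T₂
compartments (EES/CSF, T₂ = 2.78 s) nothing damps the nutation within the
0.5 s train, so the simulated Z-spectrum oscillates and can even go negative
near the water line — a numerically correct but experimentally unrepresentative
artifact: intra-voxel B₀ dispersion, shot-to-shot decoherence (a given offset
recurs only once per ~38 s dynamic) and offset schedules chosen to avoid
sideband positions keep measured DS lines smooth.

The package therefore provides two saturation models on the same generator:

* `pulse_train` — literal piecewise-exponential propagation, with thermal or
  TR-cycled initial conditions. This is the mechanistic reference used in the
  oracle tests and appropriate whenever the water T₂ is short enough
  (T₂ ≲ tsat) to damp the nutation.
* `cw_steady_state` — the exact steady state of the same Bloch-McConnell
  system under continuous irradiation at the train's amplitude average
  (0.188 µT for the default train). For slowly precessing spins a low-B1
  shaped train coherently averages to this equivalent CW field; the steady
  state is the sideband-free effective description of an acquisition running
  in a saturation steady state. This is the default for tissue-level
  predictions and the phantom.

The choice matters quantitatively: with the effective steady state the
single-compartment linewidths land at 57.0 Hz (arterial blood), 92.5 Hz
(venous blood) and 18.4 Hz (CSF). No single effective amplitude makes all
compartments simultaneously match published simulation values of this
experiment, because a pulsed train saturates short-T₂ spins with partial
power-weighting (⟨ω₁²⟩ > ⟨ω₁⟩²); the residual spread of roughly ±15% across
tissues is the irreducible envelope uncertainty and is stated as such rather
than absorbed by per-tissue calibration.

## Tissue mixing, noise, resampling

Compartment Z-spectra (each normalized to its own unsaturated signal) are
mixed at the signal level with volume fractions and water-density weights;
inter-compartment water exchange is not modelled. Blood is a 0.3/0.7
arterial/venous mixture. The shipped parameter resource carries per-tissue
relaxation times, volume fractions (GM/WM cell fractions 0.742/0.762 so the
stated constraint f_b+f_e+f_c = 1 holds exactly against 2-decimal rounding),
water densities and glucose concentrations per glycemic state; user overrides
merge by key.

Rician noise replaces S by √((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σS₀); the
default σ is 2% of S₀, applied after mixing and before resampling, matching
the acquisition order. Resampling to the 28-offset experimental grid
(±[5.0 … 0.1] ppm) uses a cubic spline and refuses to extrapolate.

## Linewidth fitting

The DS line is fitted with a single inverted Lorentzian (amplitude, center,
FWHM, baseline) by bounded trust-region least squares with deterministic
data-driven initialization: amplitude = baseline − min Z, center at the
minimum, FWHM from the half-depth crossings, baseline from the |Δω| ≥ 4 ppm
points. Bounds: FWHM ∈ [1, 1000] Hz, center ∈ [−1, 1] ppm, baseline ∈
[0.8, 1.1], amplitude ∈ [0, 1.5]. The ±10 ppm normalization acquisitions are
excluded (default window |Δω| ≤ 5 ppm). Hz conversion uses 127.731 MHz at 3 T.

A caveat the tests document explicitly: for a *mixture* whose narrow
component broadens, a free-amplitude fit converts much of that change into
fitted depth rather than width, so small mixed-tissue ΔLW values can even be
slightly negative while every component broadens; a depth-pinned fit of the
same spectra gives strongly positive values. Reported mixture ΔLW is
therefore fit-convention dependent at the sub-percent level. The deterministic
free-amplitude convention is kept throughout because it is reproducible and
fully specified.

The closed-form CW linewidth (R₁R₂² + ω₁²R₂)/R₁ under the square root, over
π, is implemented with its ω₁-dominated approximation as a flag and
cross-checked against a single-pool CW simulation (5% agreement).

## Dynamic pipeline

Normalization: per voxel per dynamic, S₀ is the mean of the *second* +10 and
−10 ppm acquisitions; non-positive S₀ masks the voxel. LW maps: one fit per
voxel per dynamic; byte-identical spectra are fitted once (exact caching —
relevant for noiseless phantoms). Baseline: mean over pre-infusion dynamics
after a single-pass ±2 SD rejection, per voxel; LW_base ≤ 5 Hz is masked to
avoid ratio blow-up. ΔLW and AUC follow their definitions; "infusion block"
is ⌈(35 g / 6.25 g·min⁻¹)/38.4 s⌉ = 9 dynamics. Failed fits are excluded from
means, never interpolated. ROI curves use a centered 3-point moving average
with edge replication.

## Phantom

Deterministic geometry (ellipsoidal GM rim / WM core, two CSF ventricles,
spherical tumor, cylindrical vessel) on a configurable grid; regions are
internally homogeneous — one simulated spectrum per region per dynamic,
broadcast to voxels, with per-voxel seeded Rician noise. Uptake is an
exponential approach from each compartment's normoglycemic toward its
hyperglycemic concentration (onset at the infusion dynamic, time constant in
dynamics); real uptake curves are measured, not modelled, so this form is a
documented stand-in. The default protocol mirrors the emulated acquisition:
32 offsets (±10 ppm twice), 40 dynamics of 38.4 s (32 × 1.2 s; the scanner's
printed 38.2 s is recorded in metadata), infusion after dynamic 8.

What passing phantom tests show — and what they do not: noiseless truth
recovery demonstrates that normalization, fitting and the ΔLW algebra are
unbiased on ideal Lorentzian-like inputs; they do not exercise motion, B₀/B₁
inhomogeneity, partial-volume mixing beyond region boundaries, or
physiological uptake shapes.

## Validation problem sizes

The shipped tests use desk-scale versions of the study conditions: 16×16×8
grids (~100–350 voxels per region), 8–12 dynamics, 10 noise seeds for the
stability property, 20 seeds for the noisy reference-table check, and 500
replicates for fitter noise robustness. The seven-tissue, two-state noiseless
reference table itself runs in well under a second.

## Known limitations

* The effective-CW steady state removes pulse-comb sidebands entirely; real
  acquisitions can retain them in long-T₂ regions (the in-vivo CSF
  discrepancy this causes is a known feature of the method).
* Readout perturbation of Mz (52° EPI flip) is not modelled.
* Mixture ΔLW magnitudes are sensitive to the Lorentzian fit convention (see
  above); single-compartment values are not.
* Hydroxyl multiplicities and the pulse envelope are literature-level
  assumptions exposed as configuration, not measured quantities.
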