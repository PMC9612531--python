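# Methods

## Problem and model

Low-intensity focused ultrasound (LIFU) applied through the skull is
attenuated and its focus displaced relative to free-water propagation.
`skullbeam` estimates both effects for a simplified head model — a flat,
homogeneous bone layer in water — across five parameters: carrier
frequency, bone thickness, trajectory angle between the beam axis and the
bone surface (90° = normal incidence), focal depth and transducer
diameter. For every sampled parameter combination the package runs two
otherwise identical simulations, one with the bone slab and one with water
only, locates the peak of the squared maximum-pressure field in a search
region on the brain side of the slab, and records

* **attenuation** — bone-run peak intensity as a percent of the water-run
  peak (a transmitted fraction: 100% means bone had no effect), and
* **refraction** — the Euclidean distance in mm between the two peak
  locations.

The resulting paired 5-D tensors form a surrogate model: a user query is
answered by multilinear interpolation instead of a fresh simulation.
"Difference in intensity" phrasings elsewhere notwithstanding, the stored
attenuation is deliberately the transmitted *fraction*, because that is the
quantity a user needs and the one consistent with sub-percent transmissions
through thick bone at 1 MHz.

## Wave solver

The solver integrates the first-order linear acoustic equations (pressure
and particle velocity, heterogeneous density and sound speed) with a
k-space pseudospectral scheme: spectral spatial derivatives on spatially
staggered grids, the dispersion correction `kappa = sinc(c_ref k dt / 2)`
with `c_ref` the scene's maximum sound speed, and a split-field perfectly
matched layer (PML) whose absorption rises with the fourth power of depth
into the layer and reaches `pml_alpha * c_ref / dx` at the outer edge
(defaults: 10 voxels, alpha 2). The acoustic density is stored split per
axis so each propagation direction can be damped independently. The time
step is `cfl * dx / c_max`; CFL defaults to 0.3. Axes may individually
omit the PML, leaving them periodic — used to realize exact plane-wave
(1-D) validation scenes inside the 2-D solver.

Absorption is handled as a stationary per-voxel loss: each simulation is
narrowband at its carrier, so the power-law absorption
`a0 (f/1 MHz)^y` (bone: 85 Np MHz⁻¹ m⁻¹, y = 1; water: the quadratic
pure-water law) is evaluated once at the carrier and applied as an
amplitude damping rate `alpha * c` on both field variables, which makes a
travelling wave decay exactly as Beer–Lambert `exp(-alpha x)` (verified to
0.7% over 50 voxels). This trades the dispersive fractional-Laplacian
operator of broadband solvers for speed while preserving amplitude physics
at the carrier; it is a fidelity difference for strongly transient fields.

### Source model

The transducer is a spherical-cap shell rasterized by marking voxels whose
centers lie within half a voxel diagonal of the defining sphere, inside
the aperture cone, and within half a voxel of the aperture radius
laterally (so the chord matches the requested diameter to one voxel). The
radius of curvature follows from the focal depth `F` and aperture radius
`a` as `R = sqrt(F² + a²)`; the geometric focus sits `F` beyond the
aperture plane.

The drive is injected additively into the split densities with the scaling
`2 dt / (N c dx)` per component, which makes an emitted plane wave carry
exactly the prescribed source pressure; `cos(omega dt / 2)` corrects the
time-staggered injection (emitted amplitude verified to 0.6%). Two
shell-specific corrections matter:

* **area normalization** — the rasterized shell is locally thicker than
  one voxel (up to √3 on diagonals), so the injected volume velocity is
  scaled by the ratio of the analytic cap area to the rasterized voxel
  area;
* **phase compensation** — each shell voxel's drive is advanced by
  `k (r - R)`, where `r` is its distance from the sphere center, so all
  contributions arrive in phase at the geometric focus. Without this the
  ±half-diagonal radial scatter of voxel centers (±0.9 rad at 6 points
  per wavelength) defocuses the cap and costs ~15% of focal amplitude.

The drive ramps on with a cosine taper over 3 carrier cycles and the
max-pressure record starts only after the ramp, excluding onset
transients. A Dirichlet source mode (pressure enforced on the shell) is
retained as an option; the additive mode is the default because the shell
then does not scatter returning waves.

## Scene geometry

Axis 0 is the beam axis at normal incidence; the cap apex sits on the
first interior voxel plane (meeting the PML) and is laterally centered.
Oblique trajectories rotate the bowl's defining sphere about the
aperture-rim point nearest the domain interior, so the focus moves away
from the PML. The bone slab is always axis-aligned — `round(d/dx)`
consecutive voxel planes starting one plane past the deepest transducer
voxel — regardless of tilt, avoiding an aliased (staircased) bone surface,
the dominant error source for voxelized skull models. The peak-search mask
covers interior voxels strictly beyond the slab's inner face; it depends
on the nominal thickness but not on whether bone is present, so paired
runs search identical regions.

## Analytic references

* **Focused-bowl axial solution** — the classic uniformly driven
  spherical-cap radiator, evaluated in the singularity-free form
  `|p(z)| = p0 k (2 h R / (r_e + z)) |sinc(k h (R - z)/(r_e + z))|`
  (`h` cap height, `r_e` distance to the rim), whose limit at the
  geometric focus is the focal gain `p0 k h`.
* **Rayleigh–Sommerfeld integral** — a numerical surface integral over the
  cap (≥10 elements per wavelength), used as an independent oracle; it
  agrees with the closed form to well under 1% RMS on the axis.
* **Three-medium slab transmission** — water–bone–water transfer-matrix
  coefficient with complex wavenumber in bone, including internal
  multiples and layer resonances.
* **Focal AUC deviation** — each axial profile restricted to its own
  contiguous −3 dB region (intensity ≥ 50% of its maximum, i.e. pressure ≥
  √0.5 of peak), area by trapezoid, deviation `100 |A_sim - A_ref|/A_ref`
  with the analytic profile as denominator.

## Validation procedures and problem sizes

Full-scale scenes are 256³ voxels at 0.5 mm (11.8 cm interior,
2.96 points per wavelength at 1 MHz, 11.86 at 250 kHz). The package's own
test and validation defaults are scaled to desk size while exercising the
same code paths:

* **Focused-bowl comparison** — 96³ voxels at 1 mm, 6 points per
  wavelength (247 kHz), three (depth, diameter) combinations with
  f-number ≲ 1 so the focal region fits the interior. Measured focal AUC
  deviations are ~1–7% (mean ~4%).
* **Convergence sweep** — the published convergence point (1 MHz, 12 mm
  bone, normal incidence) in a 2-D scene with a 40 mm depth / 40 mm
  diameter transducer, CFL {0.3, 0.1} × PPW {3, 6}. Coarsest and finest
  settings agree within 20% relative on both attenuation and refraction
  (measured: ~16% attenuation, ~6% refraction). The thick, strongly
  absorbing slab mirrors the published setting; thin slabs at low
  frequency sit near Fabry–Perot resonances where transmission varies
  steeply with thickness and convergence degrades.
* **Toy surrogate sweeps** — 2 levels per axis on 2-D scenes (≤96×80
  voxels), used for build/round-trip/query determinism checks.

## Numerical choices

* Peak ties break to the lowest linear (row-major) voxel index.
* Voxel centers are at `index * spacing`; all distances use voxel centers.
* The nearest stored simulation resolves per-axis ties toward the lower
  index.
* Query hulls are closed: boundary values are accepted; any invalid corner
  in the enclosing 2⁵ cell raises an error rather than extrapolating, and
  points outside the sampled ranges raise an out-of-range error, matching
  the tool's focus-inside-bone / outside-head semantics.
* `vis2d` upsampling uses an integer factor (default 10) with coarse nodes
  preserved exactly.
* Pre-flight validity: a point is skipped when the focal depth does not
  exceed the bone thickness (focus inside bone) or when cap height + slab
  + projected focal depth + one wavelength of margin exceeds the interior
  (focus outside the head).
* No randomness anywhere in the pipeline; rebuilds are bit-identical.
* Water absorption uses a monotone PCHIP fit in temperature to a published
  pure-water `alpha/f²` table (quadratic in frequency, default 37 °C).

## What the synthetic scenes do and do not show

The study medium is a flat homogeneous bone layer: no skull curvature, no
cortical/trabecular layering, no density heterogeneity, no shear-wave
conversion at oblique incidence (the solver is fluid-only), and no
nonlinearity or heating. Real-skull refraction and attenuation can differ
substantially from the homogeneous flat-plate prediction, so passing
validations here demonstrate solver and pipeline correctness for the
stated model, not clinical accuracy for individual subjects. CT-derived
subject-specific simulation remains the higher-fidelity alternative the
surrogate is meant to precede, not replace.

## Known limitations

* Stationary (non-dispersive) absorption; broadband pulses would see
  incorrect loss-versus-frequency behavior.
* The additive shell source is calibrated for narrowband drive; the
  `cos(omega dt/2)` and area/phase corrections assume the carrier.
* At 3 points per wavelength the focal amplitude carries a few percent of
  discretization error (the reduced convergence sweep quantifies it).
* 2-D scenes are genuinely 2-D (cylindrical, not spherical spreading);
  they validate trends and code paths, not absolute 3-D gains.
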