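# Methods

This note records the models implemented in `silkpol`, the conventions and
numerical choices behind them, and what the synthetic test-beds do and do
not establish about real measurements.

## Measurement model (dual rotating retarder)

The polarization state generator is a fixed horizontal polarizer followed
by a quarter-wave retarder at angle θ; the analyzer is a second quarter-wave
retarder at 5θ followed by a fixed horizontal polarizer. All elements are
ideal (retardance exactly 90°, polarizer transmitting ½ of unpolarized
light — an overall scale removed by m11 normalization). With the
generator-side retarder angle as the Fourier variable, the detected
intensity is a 25-coefficient truncated series in 2θ (harmonics 1..12);
this is the only reading under which the 5:1 scheme's series is complete,
since the analyzer chain contributes harmonics up to 20θ and cross terms up
to 24θ = 2·12·θ.

Element recovery does not transcribe coefficient relations: the intensity
is linear in the 16 unknown elements, `I(θk) = Σᵢⱼ cᵢⱼ(θk) mᵢⱼ`, with the
coefficient map generated from the same element chain as the forward model,
and the system is solved by least squares (condition number ≈ 13 for the
default 30 even steps over [0°, 180°)). The analytic Fourier fit is kept as
a diagnostic; the two routes agree to ~1e-15. A 3:1 rate ratio yields a
singular design (verified), which is why the classic 5:1 ratio is the
default and the solver raises a conditioning error otherwise. Retarder
retardance error and axis misalignment are not modeled; the instrument
calibration residual (≤0.01 per element on air) is therefore met trivially,
with the round trip exact to ~1e-9 or better.

## FDH statistics

Histograms use 400 uniform bins with area normalized to 1; out-of-range
pixels are clipped into the boundary bins and counted, so normalization
holds exactly. The default axis range is the physical bound [−1, 1] of
m11-normalized elements (the narrower ±0.1 display range used for
off-diagonal image colorbars is available as an option); only "400 parts"
is prescribed for the axis, so the range is a package choice.

Moments P1..P4 are computed from the raw pixel values, not the binned FDH
— the moment definitions act on the pixel random variable X, and this
removes binning bias from the derived parameters (P1/P2 from a 400-bin FDH
agree with raw moments to within one bin width; asserted in tests).
Variance uses the population denominator n (the pixel set is the
population; the n−1 correction is negligible at image scale), kurtosis is
non-excess (Gaussian → 3), and P3/P4 are returned as undefined flags — not
numbers — when the variance is zero. Derived parameters: c1_p1 is computed
from the m22/m33 means of the wash in question; d22_p1 and d23_p2 are
relative changes against the unwashed state and are exactly 0 at wash 0.

## Single-scattering kernels

Spheres use the Lorenz–Mie partial-wave series (real relative index
m = 1.56/1.0; vacuum wavelength 633 nm; no absorption anywhere, so the
albedo is 1 and Qext = Qsca), truncated at x + 4x^⅓ + 2 terms with the
logarithmic derivative by downward recurrence. Cylinders use the
infinite-circular-cylinder solution at oblique incidence ζ (angle from the
axis); scattered light lies on the cone of the incident axial angle, the
cross-polar amplitudes vanish identically at normal incidence, and the
azimuth-integrated power equals the coefficient-sum cross sections
(Parseval, checked to 1e-6). Incidence angles below 1e-3 rad of grazing are
rejected as ill-conditioned.

Amplitude-to-Mueller conversion is not transcribed from formula tables:
the Mueller matrix is computed as the exact Kronecker image of the 2×2
amplitude matrix under the Stokes map I = |E∥|²+|E⊥|², Q = |E∥|²−|E⊥|²,
U = 2Re(E∥E⊥*), V = −2Im(E∥E⊥*), with "parallel" in the scattering plane
(spheres) or the direction–axis plane (cylinders). Tests verify it against
an independent field-probing construction and the known Mie block
symmetries.

## Monte Carlo transport

Photons launch as a pencil beam at the origin along +z into a slab of
thickness 0.01 cm; boundaries are index-matched (interstitial and outside
index 1.0), so there is no Fresnel step and no internal reflection. Free
paths are Exp(μt) with μt the summed sphere/cylinder scattering
coefficients; the species at each event is chosen with probability
μᵢ/μt. The cylinder orientation is redrawn at every event from the wrapped
Gaussian (mean 0° = x-axis, default std 15°) — the ensemble-average
reading of the angular distribution; near-grazing draws (|cos| > 1−1e-9)
are rejected and redrawn.

Polarization is tracked as a Stokes vector in a local transverse frame
(explicit basis vectors, no meridian singularities). At each event the
frame is rotated into the scattering plane (spheres) or the
direction–axis plane (cylinders), the tabulated single-scattering Mueller
matrix at the sampled angles is applied, and the Stokes vector is
renormalized to unit intensity. Directions are importance-sampled from the
exact polarization-dependent scattered-intensity law — spheres: polar
angle from the tabulated M11·sinθ CDF (721 nodes, linear inversion), then
the azimuth conditional a + b·cos2φ + c·sin2φ by rejection; cylinders:
cone azimuth from the tabulated per-ζ intensity (91 axial × 360 azimuth
nodes, nearest-ζ lookup, ~1° resolution) — so unit statistical weights
keep the estimator unbiased. With albedo 1 the configured Russian roulette
(threshold 1e-4, survival 1/10) never triggers; the 10⁵ max-scatter cap is
the only active safeguard, and at optical thickness 0.8 virtually all
photons exit after a few events.

**Detection.** Photons crossing the top surface are binned by exit
position (default 64×64 pixels over a 0.4 cm square in the library;
analyses in this package use 32×32). Each exiting ray's Stokes vector is
expressed in the camera H/V basis by rotating into the meridian frame of
its exit direction and then de-rotating by the exit azimuth — the
polarization mapping of an ideal aplanatic imaging system. (A naive fixed
x-projection basis over the full hemisphere leaves a purely geometric
residual in the aggregate Q of even a perfectly isotropic medium; the
meridian/de-rotation mapping removes it exactly, which the sphere-only
block-diagonality test confirms.) Finally the analyzed U and V change
sign: the detection arm's right-handed frame has z′ = −z with a shared
horizontal x-axis, the convention in which a retro-reflected air path
calibrates to the identity matrix and backscattered diagonal elements of
depolarizing media are positive. The instrument's 15° oblique detection
arm is treated as glare avoidance and not modeled; illumination is normal.

The per-pixel Mueller image is solved linearly from the responses to the
four probing input states H, V, +45°, right-circular, then normalized by
m11 with pixels below an epsilon of 1e-6 of the peak m11 (or below a
photon-count threshold) masked. Region-level readouts use the aggregate
estimator — Stokes sums over the region, solved once — which weights every
photon equally and has far lower variance than averaging per-pixel
matrices; the per-pixel FDH route is retained as the measurement-faithful
readout.

A pencil beam is simulated rather than the ~1.8 cm illumination spot: the
extended-beam image is the spatial convolution of the pencil response, and
region-level FDH statistics are taken over the detected area either way.

## Degradation sweeps

Two seven-step parameter sweeps emulate progressive washing damage. The
surface-roughening sweep varies the sphere:cylinder scattering-coefficient
split through (10,70), (13,67), (15,65), (21,59), (22,58), (27,53),
(28,52) cm⁻¹ — the printed pairs all sum to 80 cm⁻¹, i.e. constant optical
thickness 0.8, which is why the ratio list is read as coefficients. The
fiber break-up sweep shrinks the cylinder diameter and widens the
orientation spread through (1.5 µm, 15°), (1.0, 15°), (0.9, 19°),
(0.86, 19°), (0.76, 20°), (0.68, 21°), (0.68, 22°), holding the baseline
coefficient split. Step 1 is the unwashed reference for the d-parameters.

Trend statements use replicate simulations (3 × 7×10⁴ photons per state
per step by default) with standard errors from the replicate scatter.
Observed behavior: the roughening sweep decreases c1_p1 monotonically
(≈0.50 → 0.27) with d22_p1 always negative; the break-up sweep lowers
c1_p1 end-to-end (≈0.50 → 0.32) and drives d22_p1 from 0 to ≈ −0.20.

## Synthetic image generator

`silkpol.synthetic` draws element planes with prescribed means and
variances under three textures (iid Gaussian, smoothed Gaussian field,
oriented stripes that modulate m22/m33 along a stated axis), seeded and
bit-reproducible. It emulates the first two marginal moments and simple
spatial structure of real element images — sufficient to validate the FDH
moment estimators and their sampling distributions — but not inter-element
physical constraints, speckle statistics, or instrument noise; passing
moment-recovery tests therefore validates the statistics pipeline, not the
optics.

## Problem sizes

Default analyses use a 32×32 detector over 0.4 cm, 1–2×10⁵ photons per
input state for single-medium readouts, and 3 replicates × 7×10⁴ photons
per state per sweep step; at these sizes the aggregate-route c1_p1 carries
a standard error of roughly 0.005–0.01. Tabulation resolutions (721 polar
nodes, 91×360 cylinder nodes) keep phase-function discretization below
0.5°/1°.

## Known limitations

* The slab (optical thickness 0.8) depolarizes far less than real layered
  silk windings, so simulated m22/m33 and c1_p1 magnitudes are not
  comparable to measured ones — only the trends across sweeps are
  interpreted, matching how the simulation is used.
* The break-up sweep's c1_p1 is not stepwise monotone: cylinder scattering
  has resonance structure in the size parameter, and the 0.76 µm → 0.68 µm
  step shows a reproducible small uptick (~0.04) before the final decline.
  End-to-end decline and the d22_p1 sign are the stable signatures.
* Cylinders are infinite, homogeneous and non-birefringent; spheres are
  homogeneous; there is no absorption. Fresnel boundary effects, speckle
  and time resolution are out of scope.
* The azimuth node spacing (1°) quantizes cylinder scattering angles; at
  the photon budgets used this is far below statistical error.
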