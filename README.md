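# silkpol

Quantitative characterization of the wavelength-scale microstructure of
fibrous (silk) samples from backscattering Mueller-matrix images.

Silk fabrics degrade under repeated washing, and different detergents damage
the fibers in different ways — surfactant-type products leave the ordered
fiber bundles intact, while alkaline soaps roughen fiber surfaces and
oxidizing stain removers break strands into thin, disordered fibrils. These
changes happen at the wavelength scale and are invisible to ordinary
imaging, but they reshape how polarized light scatters back from the
sample. `silkpol` implements the full computational chain for reading them
out non-destructively:

* **Mueller-matrix polarimetry** (`silkpol.polarimeter`) — the forward model
  of a dual-rotating-retarder instrument (fixed polarizers, two quarter-wave
  plates rotating at a 5:1 rate ratio) whose detected intensity is a
  truncated Fourier series `I(θ) = α₀ + Σₙ₌₁..₁₂ αₙcos2nθ + βₙsin2nθ`, and
  the inverse solve recovering all 16 elements m11..m44 from a 30-step
  intensity curve.
* **FDH moment statistics** (`silkpol.fdh`) — each element image is reduced
  to a frequency distribution histogram (400 bins, area normalized to 1)
  and the central-moment parameters P1 = E(X), P2 = Var(X),
  P3 = E(X−µ)³/σ³, P4 = E(X−µ)⁴/σ⁴ of its pixel values, plus three derived
  wash-trajectory parameters

      c1_p1  = |m22.P1 − m33.P1| / m22.P1      (anisotropy degree)
      d22_p1 = (m22ᵢ.P1 − m22₀.P1) / m22₀.P1   (depolarization-linked shift)
      d23_p2 = (m23ᵢ.P2 − m23₀.P2) / m23₀.P2   (disorder-linked widening)

  where subscript i is the i-th wash and 0 the unwashed state.
* **Sphere–cylinder Monte Carlo** (`silkpol.scattering`, `silkpol.montecarlo`)
  — polarized photon transport through a thin slab of 0.2 µm spheres
  (surface roughness, particles) and 1.5 µm infinite cylinders (fibers,
  oriented along x with a 15° Gaussian spread), indices 1.56/1.0 at 633 nm,
  with full Mie and oblique-incidence cylinder amplitude solutions.
  Degradation sweeps vary the sphere:cylinder scattering split (soap-type
  roughening) or the cylinder diameter and orientation spread (oxidative
  fiber break-up) and reproduce the measured parameter trends.

The packaged example data (`silkpol.tables`) are published P1/P2 moment
tables of silk washed 0–6 times with four detergents: fabric softener (F),
laundry powder (L), toilet soap (T) and color stain net (C).

## Worked example

Derived-parameter report for the color-stain-net wash series:

```bash
silkpol tables --series C --out report_C.csv
```

```
       c1p1   d22p1  d23p2  aniso_diff  m22_p2_fold  abs_dP1_m12 ...
wash
0    0.9387  0.0000 0.0000      0.5210       1.0000       0.0000
1    0.8969  0.0486 0.0500      0.5220       1.0000       0.0020
2    0.9340  0.1459 0.3500      0.5940       1.2083       0.0050
3    0.9226  0.0937 0.4500      0.5600       1.3333       0.0020
4    0.8957  0.0541 0.5500      0.5240       1.6667       0.0040
5    0.7982  0.0090 2.0500      0.4470       3.0417       0.0090
6    0.5873 -0.2054 2.6500      0.2590       4.4583       0.0240
```

Reading the numbers: the m22−m33 mean difference (`aniso_diff`) collapses
from 0.521 to 0.259 — the ordered, strongly anisotropic fiber alignment is
being destroyed; `c1p1` falls from ~0.94 to 0.59 accordingly. `d22p1`
turns negative by the sixth wash (rising depolarization) and `d23p2` grows
past 2.6 while the m22 variance rises 4.5-fold (`m22_p2_fold`) — the
element distributions broaden as fiber orientation disperses. For the
gentle detergents (`--series F` or `L`) all three parameters stay nearly
flat and `c1p1` remains around 0.9.

Simulate the microstructural interpretation (both degradation sweeps,
Monte Carlo at 2×10⁵ photons per input state):

```bash
silkpol demo --photons 200000 --seed 0 --out-dir demo-out
```

which writes `sweep_toilet_soap.csv`, `sweep_color_stain_net.csv`, a
parameter plot and a JSON provenance record. Other subcommands:
`silkpol simulate` (one medium → 16-page TIFF Mueller image),
`silkpol analyze` (image → FDH moments CSV), `silkpol reconstruct`
(rotating-retarder intensity CSV → Mueller matrix) and `silkpol phasefun`
(single-scattering phase functions).

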