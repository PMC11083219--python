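# mosaicfocus

Monte Carlo simulation of hard-X-ray focusing with ellipsoidally bent mosaic
graphite crystals (HOPG/HAPG), and of the X-ray fluorescence imaging (XFI)
sensitivity achievable with such an optic on a benchtop tungsten-tube system.

## Who this is for

People designing or evaluating benchtop XFI / XRF instrumentation: the
package answers, by simulation, how well a rotationally symmetric graphite
monochromator focuses the W Kα lines (~59 keV) of a filtered 150 kVp tube,
and what contrast-agent mass (Pd, Ba nanoparticle surrogates) that focused
beam can detect in a mouse-scale object at a given dose.

## The physics in brief

**Mosaic Bragg diffraction.** A mosaic crystal is an assembly of near-perfect
crystallite domains whose plane normals scatter about the surface normal
with a Lorentzian distribution W(Δ; m) of FWHM m (the mosaic spread).  The
diffraction coefficient per unit path is σ(Δ) = W(Δ; m) Q, with the
kinematical power per unit volume

    Q = (r_e |F_hkl| / V)^2 · λ^3 / sin 2θ_B · (1 + cos^2 2θ_B)/2,

θ_B = arcsin(nλ/2d) the Bragg angle (d = 0.3354 nm for graphite (002)).
The closed-form two-beam peak reflectivity of a layer of thickness T,

    r = a_p / (1 + a_p + sqrt(1+2a_p) · coth(b_p · sqrt(1+2a_p))),
    a_p = W(0;m) Q / μ_tot,   b_p = T μ_tot / sin θ_B,

is implemented alongside a Monte Carlo transport model in which a virtual
crystallite is sampled at every candidate interaction and the photon
reflects specularly about its normal; multiple diffraction orders of
scattering, Compton and photoelectric events compete inside the crystal.

**The optic.**  An ellipsoid of revolution (waist radius a0 = 10 mm, axial
semi-axis b0 = 500 mm) carries a 40 mm crystal band at its waist; source and
target sit on-axis, 320 mm on either side (one-to-one geometry), so photons
graze the crystal at ~1.79°, the 59 keV Bragg angle.  A Pb beam-stop blocks
the direct beam.  The focal spot, intensity gain over the direct beam, and
spectral bandwidth ΔE5% are computed from end-to-end traces.

**XFI sensitivity.**  A voxelized soft-tissue torso surrogate with a
contrast-loaded tumor sphere is scanned by the focused beam; K fluorescence
and scatter reach a ring of six backward-looking SDD or CdTe detectors with
a Fano + electronic-noise resolution model and (for CdTe) Cd/Te escape
peaks.  Spectra are fitted with fixed-shape K-line Gaussians plus a cubic
background, and detectability is quantified by the significance
Z = N_F / sqrt(N_B).  Tissue doses are scored from local energy deposits.

## Worked example

A rocking scan of the m = 0.12°, 80 μm crystal at 59 keV (51 angles,
2×10^4 photons each):

```
$ mosaicfocus rocking-curve --m 0.12 --energy 59 --n 20000 --seed 42 --out rc
{"delta_fwhm_deg": 0.2539, "r_peak": 0.1008, "r_integrated_mrad": 0.6298}
```

The curve width δ ≈ 0.25°, peak reflectivity ≈ 10% (the closed-form
two-beam value for this crystal is 16.4%; the Monte Carlo value is lower
because multiple reflections and the crystallite-orientation sampling
redistribute photons out of the reflected beam), and integrated reflectivity
≈ 0.63 mrad.  `rc/curve.csv` holds the 51-point curve.

One XFI scan step on a 5 mm liver-depth tumor loaded with 0.05 wt% Pd in
*low-dose* mode (2.7×10^7 photons per step, here estimated from 10^5 traced
histories):

```
$ mosaicfocus xfi --mode low --element Pd --wt 0.05 --diameter 5 \
      --depth liver --n 100000 --seed 42 --out xfi
{"N_F": 70.9, "N_B": 1.65, "Z": 55.1, ... "contrast_mass_ug": 34.6}
```

N_F ≈ 71 fitted Pd Kα counts over N_B ≈ 1.7 background counts in the
±3σ window gives Z ≈ 55 — far above the Z = 5 detection threshold, as
expected for 34.6 μg of Pd in the sphere.  Per-detector spectra and a
`dose.csv` (tissue, mass, Gy per step) are written alongside.

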