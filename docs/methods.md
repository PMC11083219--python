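# Methods

This note records the models implemented in `mosaicfocus`, their
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.  Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## X-ray data backbone (`xray_data`)

Attenuation is assembled per element from three channels:

* **Photoelectric** — frozen tables in `_attenuation_tables.py`, interpolated
  log-log.  Low-Z elements (H…Ca, Al, Si) are anchor tables transcribed from
  standard compilations; the heavy elements (Pd, Cd, Te, Ba, Hf, W, Pb) come
  from a parametric model τ ∝ Z^4.6/(A E³) above the K edge with an edge
  jump ratio J(Z) = 9.2 − 0.058 Z and an E⁻³ continuation below, calibrated
  at the lead 100 keV point.  K edges are represented by duplicated grid
  energies.  Expected accuracy: a few percent for low Z, 10–20% for the
  parametric elements.  L-subedge fine structure (below ~16 keV for Hf/W/Pb)
  is smoothed over; photons in that regime are absorbed in any of the
  geometries simulated here regardless of the exact coefficient.
* **Incoherent (Compton)** — free-electron Klein–Nishina × Z/A.  No Doppler
  broadening and no incoherent scattering function S(q, Z); this
  overestimates Compton attenuation at low energy/low Z by up to ~20% at
  10 keV (≲3% above 50 keV, where it matters here).
* **Coherent (Rayleigh)** — Thomson cross section integrated over a screened
  form factor f(s, Z) = Z(1+(s/s₀)²)^{−3/2}, s₀ = 0.2014 Z^{1/3} Å⁻¹,
  normalized against the Cromer–Mann carbon factor.  The same form factor
  drives Rayleigh angle sampling.

Two "total" conventions coexist by design: `total` (photoelectric +
Compton) enters the mosaic reflectivity formula; `transport_total` (all
three) drives free-path sampling.

Fluorescence: single K-vacancy physics only — line energies, Kα/Kβ ratios
and yields ω_K are authored constants for Pd, Cd, Te, Ba, Hf, W, Pb.  No
L-series emission, no cascades.

Graphite density defaults to 2.26 g/cm³ (ideal HOPG) and is configurable,
since pyrolytic graphite densities vary and μ_tot feeds b_p directly.
Soft tissue and adipose use ICRP compositions at 1.06 and 0.95 g/cm³.

## Mosaic crystal (`mosaic_crystal`, `mc_transport`)

The mosaic distribution W(Δ; m) is the unit-normalized Lorentzian with
FWHM m — the standard convention for low-mosaicity graphite; the garbled
printed normalization of the source formula was replaced by this one.  The
structure factor |F₀₀₂| = 4 f₀(1/2d) = 17.30 electrons is computed from
Cromer–Mann carbon form factors with four atoms per hexagonal cell and no
Debye–Waller factor; the missing thermal factor is the main reason the
closed-form reflectivities are quoted with ±10% confidence.  The
crystallite thickness t₀ cancels exactly between the layer reflecting power
and the single-domain integrated power and is retained as metadata only.

**Transport model.**  Inside crystal volumes the Rayleigh channel is
replaced by diffraction.  The crystal walk is Woodcock (null-collision)
tracking under the majorant Q·W(0; m): at each candidate vertex a virtual
crystallite is drawn (independent Lorentzian tilts about two tangential
axes, truncated at ±5m — untruncated tails would produce unphysical
near-normal domains; the bound is configurable), the diffraction
coefficient is evaluated at the Bragg mismatch *to that crystallite*, and
an accepted diffraction reflects the photon specularly about the sampled
crystallite normal.  Marginalizing over crystallites makes the effective
coefficient Q·(W∗W)(Δ): FWHM 2m and half the peak height of the analytic
σ(Δ) = Q·W(Δ).  This per-vertex sampling is deliberate: it is the discrete
"virtual crystallite" algorithm of the simulation framework this package
re-implements, and it is what produces Monte Carlo rocking curves that are
wider (δ ≈ 0.25° for m = 0.12° at 59 keV) and lower (R_peak ≈ 10% vs the
16.4% two-beam closed form) than theory — the behavior the reference
framework also reports.  Multiple diffraction per history is allowed;
photons crossing the back face enter the substrate, which is treated as an
absorber (substrate backscatter cannot re-enter the diffracted tally under
the counting convention below).

**Counting convention.**  A rocking-scan history counts as reflected when
it diffracted at least once and re-emerged through the entrance face at any
angle (no collimation).  Photons that only Compton-scattered are excluded;
including them would add a flat albedo baseline that the reflectivity
definition does not contain.

**Known limitation.**  With a strictly parallel beam the model gives
δ ≈ 0.25° (59 keV) against the published 0.30°±0.05, and at 8.03 keV it
gives δ ≈ 0.30° / R_peak ≈ 35% against published 0.6° / 21%.  The published
scans quote a 320 μm source, i.e. a finite divergence the parallel-beam
contract omits; the 59 keV metrics remain inside their stated tolerances,
the 8.03 keV ones do not and are not asserted numerically.

## Ellipsoidal optic (`optics_geometry`)

The optic is an ellipsoid of revolution with waist (transverse semi-axis)
a0 = 10 mm and axial semi-axis b0 = 500 mm, carrying a 40 mm crystal band
centered on the waist.  Source and target sit **on axis**, each 320 mm from
the band center — *not* at the geometric foci (±499.9 mm).  This follows
the published incidence-angle parametrization and its numbers: the
configuration yields a mean grazing angle of 1.79°–1.80° with ~0.04°
spread across the band (a confocal ellipsoid would give a spread of ~0.01°,
inconsistent with the quoted ±0.1°), and its spherical aberration — rays
from the band ends miss the axis crossing by up to ~0.7 mm — is what sets
the focal-spot scale together with the 1:1 source image and the mosaic
deflections.  A strictly confocal constructor is provided and is used as
the geometric oracle: with zero mosaic spread and specular reflection every
ray from one focus passes the other to <10⁻¹⁰ mm.

The beam-stop is one perfectly absorbing Pb disc of diameter 17.8 mm in the
band-center plane: it shadows the focal plane out to 17.8 mm radius against
direct rays while clearing the band illumination and the reflected cone
(which cross that plane at ≥9.4 mm radius).  The published "external
14.8 mm / central 17.8 mm" pair is self-inconsistent as printed; the
14.8 mm element is absorbed into the source-side collimation, which the
sampler realizes by emitting only into the annular cone subtending the
band (each photon weighted Ω/4π relative to an isotropic source).
Shields are perfect absorbers (conservative and fast); a full-transport
switch was judged unnecessary for any asserted quantity.

The thin bent crystal is traversed in a local planar-slab approximation at
the hit point: over the ~2.5 mm grazing path the meridional surface normal
rotates by only ~0.25 mrad (radius b0²/a0 ≈ 10 m), far below the mosaic
spread.  Exits are mapped back to the global frame; up to three band
re-hits are followed.

## Tube source (`tube_source`)

Kramers continuum (E_max − E)/E with a single effective anode
self-filtration path (0.012 mm W) and a characteristic-line fraction
(6.5% of unfiltered photons in the W K lines), both multiplied by the
0.4 mm Hf filter transmission whose K edge at 65.35 keV carves the passband
around W Kα and removes Kβ.  The two shape parameters were calibrated
*once* against the published direct-beam bandwidth (ΔE5% ≈ 16.5 keV) and
then frozen; no electron transport, heel effect or off-focal radiation is
modeled, and the absolute flux (9.7×10⁷ photons·mm⁻²·s⁻¹ at 300 W) is a
bookkeeping constant, not an output.

**Bandwidth metric.**  The characteristic lines are delta-sharp, so "full
width at 5% of maximum" on a raw 0.1 keV histogram would measure the tally
bin width, not the spectrum.  `bandwidth_5pct` therefore evaluates the
metric on a Gaussian-smoothed density (σ = 0.8 keV, an analysis parameter
standing in for the effective spectral resolution of the published
histograms).  Focused-beam spectra are tallied within the central 1 mm² of
the focal plane — the published comparison quantity — which is also what
monochromatizes the beam: off-Bragg energies exit at shifted angles and
land outside the central square.

## Focusing analysis (`focusing_analysis`)

Focal maps use 20 μm pixels over ±5 mm.  The cross-section FWHM averages
the central 5 pixel rows (0.1 mm) and smooths by 2.5 px before half-max
interpolation: the focal distribution is a sharp cusp on a broad halo and a
raw one-pixel slice is dominated by counting noise.  The projection FWHM is
the plain marginal.  The gain divides focused by direct counts in the
central 1 mm² within ±0.25 keV of Kα1, with identical source sampling and
distances and per-source-photon weights on both sides.  Problem sizes: the
acceptance run traces 4×10⁶ source photons (focused) and 10⁶ (direct),
which holds the stochastic scatter of the cross-section FWHM to ~0.01 mm
and of the gain to ~2%.

With these estimators the model yields cross-section/projection FWHM
≈ 0.52/0.67 mm (published: 0.6/0.84), gain ≈ 17 (14), ΔE5% ≈ 6.4 keV
(5.8) for m = 0.12° and a 320 μm source — all inside the stated
tolerances, with the spot-size values toward the narrow edge; candidate
contributors are the perfect figure of the simulated substrate and the
absorbing-shield simplification.

## XFI pipeline (`xfi_sensitivity`)

**Phantom.**  A homogeneous ICRP soft-tissue elliptical cylinder (20 mm
dorsoventral thickness, 24 mm width) in a 1 mm acrylic mount with an
optional 0.5 mm adipose skin shell, voxelized at 0.2 mm; the tumor is a
sphere of the supported diameters (0.5–10 mm) loaded with Pd or Ba at
0.0033–1 wt%, its center at the scan origin.  "Organ" placement is a depth:
subcutaneous (tangent to the entry surface), liver ≈ 5 mm, kidney ≈ 13 mm —
flagged approximations, since the anatomical model the published study used
is out of scope here.  What the surrogate does *not* emulate: organ
composition contrast, bone, the full-body scatter volume, and anatomical
asymmetry.  Passing tests therefore validate mechanisms and trends
(Z scaling with loading, size, dose mode; window background ordering), not
organ-specific detection limits.

**Beam surrogate.**  By default the focused beam is parametric: Gaussian
0.6 mm FWHM spot converging on the target at the 1.79° ring angle, energies
= the Kα doublet (77%) plus the continuum band frozen from this package's
own 4×10⁶-photon focusing run (23%).  A full end-to-end trace per phantom
run is possible but decouples poorly from XFI statistics; the phase-space
route exists for users who want it.

**Transport.**  Woodcock tracking on the voxel grid with per-material
log-energy lookup tables; channels photoelectric / Compton / Rayleigh;
contrast-element K fluorescence with probability ω_K when the photoelectric
event lands on the contrast element above its edge (tissue-element
fluorescence is sub-4 keV and treated as local deposit).  Energy cutoff
2 keV.  Kerma approximation throughout: interaction energy transfer is
deposited locally, justified below 150 keV where secondary-electron ranges
are below the voxel pitch.

**Variance reduction.**  `forced_detection` turns on a next-event
estimator: every fluorescence vertex contributes Ω_det/4π × e^(−τ) to each
detector, every Compton vertex contributes the Klein–Nishina angular
density toward each detector at the angle-shifted energy, and photons whose
last vertex made such a contribution are excluded from uncollided analog
tallies (no double counting).  Rayleigh vertices make no forced
contribution (backward coherent scattering is negligible); their analog
arrivals are counted.  Path attenuation uses a 24-step ray march.

**Detectors.**  Six sensors aimed at the origin: a central pair at 26 mm
and an upper/lower quad at 32 mm, on a cone 140° (SDD) or 150° (CdTe) from
the beam direction — one concrete reading of the published "rows at polar
30°" arrangement.  Response: absorption efficiency from the sensor
attenuation at normal incidence; Cd/Te Kα escape branches with a half-space
escape factor; Gaussian blur with FWHM²(E) = 2.355²·F·ε_pair·E +
(2.355·ENC)², (F, ε_pair) = (0.115, 3.62 eV) Si / (0.089, 4.43 eV) CdTe,
ENC = 75 eV default.  Si escape (1.74 keV, ω_K = 0.047) is neglected.
Compton interactions inside the sensor (partial deposits ≤ ~16 keV for the
energies present) are not modeled.

**Fitting and significance.**  Summed-detector spectra (per-detector is an
option) are fitted by linear least squares with one free scale per element
— Gaussians at the K-line energies, widths from the resolution model,
amplitudes tied by emission probability × detector efficiency — plus a
cubic polynomial on a conditioned abscissa.  N_F and N_B integrate the line
model and the polynomial over ±3σ_det around the intensity-weighted Kα
centroid; Z = N_F/√N_B with a one-tailed Gaussian p-value.  Simulated
spectra are expectation-scaled: n_sim traced histories are weighted to the
nominal photons-per-step (2.7×10⁷ low-dose, 2.7×10⁸ high-dose), so fitted
counts estimate the experiment's expectation; no multiple-testing
adjustment is applied across concentration grids.

**Limitation (Pd vs Ba ordering).**  In the full-anatomy study the Ba Kα
window sits on a multiple-Compton background that Pd's does not, making Pd
strictly more sensitive.  The slim surrogate reproduces the mechanism —
with no contrast loaded, background around 32 keV exceeds background
around 21 keV by well over 3× (three to four successive backscatters of a
~59 keV beam reach 30–37 keV; ~21 keV needs six or more) — but not the
resulting Z ordering: the surrogate's 32 keV floor is too thin relative to
each element's own scattered-fluorescence shoulder, and Ba's higher
absorption cross-section at 59 keV wins.  Detection-limit magnitudes do
land near the published scale (Z ≈ 5–8 at 0.01 wt% for a 5 mm subcutaneous
target in low-dose mode).

## Numerics and reproducibility

Every stochastic routine takes a `numpy.random.Generator`; identical seeds
give bit-identical runs (asserted).  Rejection loops (Klein–Nishina,
Rayleigh) are vectorized over the pending set and converge in a handful of
rounds.  Stuck-history guards: 500 steps in the crystal slab, 300 in the
phantom, 10⁴ in the generic tracker; leftovers are terminated and recorded.
Degenerate inputs (flat profiles, curves that never cross half maximum,
empty tallies) warn or raise rather than returning silent numbers.
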