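"""Mosaic-crystal Bragg diffraction physics.

A mosaic crystal is treated as an assembly of small, nearly perfect
crystallite domains whose plane normals scatter about the mean surface
normal with a Lorentzian angular distribution of FWHM ``m`` (the mosaic
spread).  The module provides:

* the Bragg angle theta_B = arcsin(n lambda / 2 d) for the (002) graphite
  reflection (d = 0.3354 nm),
* the normalized Lorentzian mosaic distribution W(Delta; m),
* the kinematical diffraction power per unit volume Q (structure factor from
  Cromer-Mann carbon form factors, 4 atoms per hexagonal cell, no
  Debye-Waller factor),
* the per-unit-path diffraction coefficient sigma = W * Q (the crystallite
  thickness t0 appearing in the layer reflecting-power expressions cancels
  between the layer power and the single-domain integrated power, so it is
  metadata only),
* the closed-form two-beam peak reflectivity
  r = a_p / (1 + a_p + sqrt(1+2 a_p) coth(b_p sqrt(1+2 a_p))),
  a_p = W(0;m) Q / mu_tot, b_p = T mu_tot / sin(theta_B), with mu_tot the
  photoelectric+Compton attenuation,
* Lorentzian sampling of crystallite orientations (truncated at +/-5m, since
  the untruncated tails would produce unphysical near-normal domains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as const
from .xray_data import (
    MaterialSpec,
    carbon_form_factor,
    energy_to_wavelength,
    get_material,
    mass_attenuation,
)

__all__ = [
    "MosaicCrystalSpec",
    "DiffractionConstants",
    "graphite_diffraction_constants",
    "bragg_angle",
    "bragg_angle_rad",
    "mosaic_pdf",
    "kinematical_Q",
    "scattering_coefficient",
    "peak_reflectivity_theoretical",
    "sample_crystallite_tilts",
    "sample_crystallite_normal",
    "CRYSTAL_PRESETS",
    "get_preset",
]

# graphite hexagonal cell: a = 2.461 A, c = 2 d_002
_GRAPHITE_A_ANGSTROM = 2.461
#: Lorentzian tilt sampling is truncated at +/- TRUNCATION_FWHM * m
TRUNCATION_FWHM = 5.0


@dataclass(frozen=True)
class MosaicCrystalSpec:
    """Mosaic crystal layer parameters.

    ``mosaic_fwhm_deg`` is the FWHM of the crystallite orientation
    distribution; ``thickness_um`` the layer thickness; ``crystallite_um``
    is informational only (it cancels in the diffraction coefficient).
    """

    mosaic_fwhm_deg: float
    thickness_um: float
    d_spacing_nm: float = 0.3354       # graphite (002)
    hkl: tuple[int, int, int] = (0, 0, 2)
    order: int = 1
    crystallite_um: float = 1.0
    substrate: str = "aluminum"
    truncation: float = TRUNCATION_FWHM

    def __post_init__(self):
        if self.mosaic_fwhm_deg <= 0 or self.thickness_um <= 0:
            raise ValueError("mosaic spread and thickness must be positive")
        if self.d_spacing_nm <= 0 or self.order < 1:
            raise ValueError("invalid lattice parameters")

    @property
    def mosaic_fwhm_rad(self) -> float:
        return math.radians(self.mosaic_fwhm_deg)

    @property
    def thickness_cm(self) -> float:
        return self.thickness_um * 1e-4

    @property
    def d_spacing_angstrom(self) -> float:
        return self.d_spacing_nm * 10.0


@dataclass(frozen=True)
class DiffractionConstants:
    """Kinematical-theory inputs: |F_hkl| (electrons), cell volume, r_e."""

    structure_factor: float
    cell_volume_nm3: float
    r_e_nm: float = const.R_E_ANGSTROM / 10.0

    def __post_init__(self):
        if min(self.structure_factor, self.cell_volume_nm3, self.r_e_nm) <= 0:
            raise ValueError("diffraction constants must be positive")


def graphite_diffraction_constants(spec: MosaicCrystalSpec) -> DiffractionConstants:
    """|F_002| and cell volume for the graphite (002) reflection.

    All four atoms of the hexagonal cell sit on z = 1/4 and 3/4 planes; for
    l = 2 each contributes a phase of -1, so |F_002| = 4 f0(s) evaluated at
    s = sin(theta_B)/lambda = 1/(2 d).  No thermal (Debye-Waller) factor.
    """
    s = 1.0 / (2.0 * spec.d_spacing_angstrom)
    f0 = carbon_form_factor(s)
    c = 2.0 * spec.d_spacing_angstrom
    vol_a3 = math.sqrt(3.0) / 2.0 * _GRAPHITE_A_ANGSTROM**2 * c
    return DiffractionConstants(structure_factor=4.0 * f0, cell_volume_nm3=vol_a3 * 1e-3)


def bragg_angle_rad(energy_kev, spec: MosaicCrystalSpec):
    """Bragg angle in radians; raises if the reflection does not exist."""
    lam = energy_to_wavelength(energy_kev)
    ratio = spec.order * np.asarray(lam) / (2.0 * spec.d_spacing_angstrom)
    if np.any(ratio > 1.0):
        raise ValueError(
            "no Bragg reflection: n*lambda/2d > 1 (energy too low for this order)"
        )
    out = np.arcsin(ratio)
    return float(out) if np.isscalar(energy_kev) else out


def bragg_angle(energy_kev, spec: MosaicCrystalSpec):
    """Bragg angle in degrees for photon energy in keV."""
    return np.degrees(bragg_angle_rad(energy_kev, spec))


def mosaic_pdf(delta_rad, fwhm_rad):
    """Unit-normalized Lorentzian W(Delta; m) with FWHM ``m`` (radians)."""
    if fwhm_rad <= 0:
        raise ValueError("mosaic FWHM must be positive")
    x = 2.0 * np.asarray(delta_rad) / fwhm_rad
    out = 2.0 / (np.pi * fwhm_rad) / (1.0 + x * x)
    return float(out) if np.isscalar(delta_rad) else out


def kinematical_Q(energy_kev, spec: MosaicCrystalSpec,
                  consts: DiffractionConstants | None = None):
    """Average diffraction power per unit volume Q (1/cm).

    Q = (r_e |F|/V)^2 * lambda^3 / sin(2 theta_B) * (1 + cos^2 2theta_B)/2
    for an unpolarized beam.
    """
    if consts is None:
        consts = graphite_diffraction_constants(spec)
    lam = np.asarray(energy_to_wavelength(energy_kev))  # Angstrom
    tb = bragg_angle_rad(energy_kev, spec)
    two_tb = 2.0 * np.asarray(tb)
    vol_a3 = consts.cell_volume_nm3 * 1e3
    re_a = consts.r_e_nm * 10.0
    prefac = (re_a * consts.structure_factor / vol_a3) ** 2  # 1/A^2
    pol = 0.5 * (1.0 + np.cos(two_tb) ** 2)
    q_per_angstrom = prefac * lam**3 / np.sin(two_tb) * pol
    out = q_per_angstrom * 1e8  # 1/A -> 1/cm
    return float(out) if np.isscalar(energy_kev) else out


def scattering_coefficient(delta_rad, energy_kev, theta0_rad,
                           spec: MosaicCrystalSpec,
                           consts: DiffractionConstants | None = None):
    """Diffraction coefficient per unit crystal *thickness*, sigma (1/cm).

    sigma = W(Delta; m) Q / cos(theta0), with theta0 the angle between the
    photon direction and the layer normal.  Expressed per unit path length
    (as used in transport) the 1/cos(theta0) factor is simply the geometric
    path-per-thickness ratio.  The crystallite thickness t0 cancels exactly
    between the layer reflecting power (proportional to 1/t0) and the
    single-domain integrated power (proportional to t0) and does not appear.
    """
    ct = np.cos(np.asarray(theta0_rad))
    if np.any(ct <= 0):
        raise ValueError("cos(theta0) must be positive inside the layer")
    w = mosaic_pdf(delta_rad, spec.mosaic_fwhm_rad)
    q = kinematical_Q(energy_kev, spec, consts)
    out = w * q / ct
    return float(out) if np.isscalar(delta_rad) and np.isscalar(energy_kev) else out


def peak_reflectivity_theoretical(spec: MosaicCrystalSpec, energy_kev: float,
                                  consts: DiffractionConstants | None = None,
                                  crystal_material: MaterialSpec | None = None) -> float:
    """Two-beam peak reflectivity at Delta = 0 for a layer of thickness T.

    Uses mu_tot = photoelectric + Compton attenuation of the crystal material
    (coherent scattering is excluded by convention here: it stays within the
    diffraction system rather than removing photons from it).
    """
    if crystal_material is None:
        crystal_material = get_material("graphite")
    mu = mass_attenuation(crystal_material, energy_kev, "total") * crystal_material.density
    w0 = mosaic_pdf(0.0, spec.mosaic_fwhm_rad)
    q = kinematical_Q(energy_kev, spec, consts)
    tb = bragg_angle_rad(energy_kev, spec)
    a_p = w0 * q / mu
    b_p = spec.thickness_cm * mu / math.sin(tb)
    root = math.sqrt(1.0 + 2.0 * a_p)
    return a_p / (1.0 + a_p + root / math.tanh(b_p * root))


# ---------------------------------------------------------------------------
# Crystallite orientation sampling
# ---------------------------------------------------------------------------

def sample_crystallite_tilts(fwhm_rad: float, size: int, rng: np.random.Generator,
                             truncation: float = TRUNCATION_FWHM) -> np.ndarray:
    """Sample Lorentzian tilt angles with FWHM m, truncated at +/- truncation*m.

    Inverse-CDF sampling of the truncated Lorentzian; returns shape (size,).
    """
    if fwhm_rad <= 0:
        raise ValueError("mosaic FWHM must be positive")
    half = fwhm_rad / 2.0
    umax = math.atan(truncation * fwhm_rad / half)  # = atan(2*truncation)
    u = rng.uniform(-umax, umax, size=size)
    return half * np.tan(u)


def sample_crystallite_normal(fwhm_rad: float, mean_normal, rng: np.random.Generator,
                              truncation: float = TRUNCATION_FWHM,
                              size: int | None = None) -> np.ndarray:
    """Perturb ``mean_normal`` by independent Lorentzian tilts about two
    tangential axes; returns unit vectors of shape (size, 3) or (3,).

    A zero (or effectively zero) mosaic spread returns the mean normal.
    """
    n = np.asarray(mean_normal, dtype=float)
    n = n / np.linalg.norm(n)
    count = 1 if size is None else size
    # tangential basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    if fwhm_rad < 1e-15:
        out = np.tile(n, (count, 1))
        return out[0] if size is None else out
    a1 = sample_crystallite_tilts(fwhm_rad, count, rng, truncation)
    a2 = sample_crystallite_tilts(fwhm_rad, count, rng, truncation)
    vec = (
        n[None, :]
        + np.tan(a1)[:, None] * t1[None, :]
        + np.tan(a2)[:, None] * t2[None, :]
    )
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return vec[0] if size is None else vec


# ---------------------------------------------------------------------------
# Presets: the three crystal configurations studied with this optic
# ---------------------------------------------------------------------------

CRYSTAL_PRESETS: dict[str, MosaicCrystalSpec] = {
    "m012": MosaicCrystalSpec(mosaic_fwhm_deg=0.12, thickness_um=80.0),
    "m024": MosaicCrystalSpec(mosaic_fwhm_deg=0.24, thickness_um=100.0),
    "m046": MosaicCrystalSpec(mosaic_fwhm_deg=0.46, thickness_um=120.0),
}


def get_preset(name: str) -> MosaicCrystalSpec:
    try:
        return CRYSTAL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown crystal preset {name!r}; known: {sorted(CRYSTAL_PRESETS)}"
        ) from None
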