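"""Element and material X-ray data: attenuation, fluorescence, conversions.

This is the data backbone of the package.  Photoelectric cross sections come
from the frozen tables in :mod:`mosaicfocus._attenuation_tables`, incoherent
(Compton) scattering uses the free-electron Klein-Nishina cross section
scaled by Z/A, and coherent (Rayleigh) scattering integrates the Thomson
differential cross section over a screened atomic form factor.  Mixtures
follow the standard mass-fraction mixture rule.

Two "total" conventions coexist deliberately:

``total``
    photoelectric + Compton.  This is the attenuation entering the mosaic
    crystal reflectivity formula, where coherently scattered photons are not
    lost from the diffraction channel.
``transport_total``
    photoelectric + Compton + Rayleigh, used for free-path sampling in the
    Monte Carlo transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import constants as const
from ._attenuation_tables import (
    CARBON_CROMER_MANN_A,
    CARBON_CROMER_MANN_B,
    CARBON_CROMER_MANN_C,
    ELEMENT_PROPS,
    K_EDGE_KEV,
    K_FLUORESCENCE,
    PE_TABLES,
)

__all__ = [
    "MaterialSpec",
    "FluorescenceLine",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "mass_attenuation",
    "element_mass_attenuation",
    "fluorescence_lines",
    "klein_nishina_total_cm2",
    "carbon_form_factor",
    "get_material",
    "register_material",
    "load_materials_yaml",
    "MATERIALS",
    "K_EDGE_KEV",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialSpec:
    """A homogeneous material: elemental mass fractions and bulk density."""

    name: str
    composition: tuple[tuple[str, float], ...]
    density: float  # g/cm^3

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(frac for _, frac in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1"
            )
        for sym, _ in self.composition:
            if sym not in ELEMENT_PROPS:
                raise KeyError(f"unknown element {sym!r} in material {self.name!r}")

    def with_contrast(self, element: str, wt_fraction: float) -> "MaterialSpec":
        """Return this material loaded with ``wt_fraction`` of a contrast element.

        The host composition is scaled by (1 - w); the density is kept at the
        host value (dilute loading).
        """
        if not 0 <= wt_fraction < 1:
            raise ValueError("wt fraction must be in [0, 1)")
        if wt_fraction == 0:
            return self
        comp = [(s, f * (1 - wt_fraction)) for s, f in self.composition]
        comp.append((element, wt_fraction))
        return MaterialSpec(
            name=f"{self.name}+{element}{wt_fraction:g}",
            composition=tuple(comp),
            density=self.density,
        )


@dataclass(frozen=True)
class FluorescenceLine:
    element: str
    label: str          # Ka1, Ka2, Kb1
    energy: float       # keV
    probability: float  # relative emission probability within the K series
    omega_k: float      # K-shell fluorescence yield


# ---------------------------------------------------------------------------
# Energy / wavelength
# ---------------------------------------------------------------------------

def energy_to_wavelength(energy_kev):
    """Photon wavelength in Angstrom for energy in keV (lambda = hc/E)."""
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("photon energy must be positive")
    out = const.HC_KEV_ANGSTROM / e
    return float(out) if np.isscalar(energy_kev) else out


def wavelength_to_energy(wavelength_angstrom):
    """Inverse of :func:`energy_to_wavelength`."""
    lam = np.asarray(wavelength_angstrom, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = const.HC_KEV_ANGSTROM / lam
    return float(out) if np.isscalar(wavelength_angstrom) else out


# ---------------------------------------------------------------------------
# Cross sections
# ---------------------------------------------------------------------------

def klein_nishina_total_cm2(energy_kev):
    """Total Klein-Nishina cross section per electron, cm^2."""
    eps = np.asarray(energy_kev, dtype=float) / const.ELECTRON_REST_KEV
    # series expansion below eps ~ 0.01 to avoid cancellation
    eps = np.atleast_1d(eps)
    out = np.empty_like(eps)
    small = eps < 0.01
    e_s = eps[small]
    out[small] = const.SIGMA_THOMSON_CM2 * (
        1 - 2 * e_s + 5.2 * e_s**2 - 13.3 * e_s**3
    )
    e_l = eps[~small]
    t1 = (1 + e_l) / e_l**2 * (
        2 * (1 + e_l) / (1 + 2 * e_l) - np.log(1 + 2 * e_l) / e_l
    )
    t2 = np.log(1 + 2 * e_l) / (2 * e_l)
    t3 = (1 + 3 * e_l) / (1 + 2 * e_l) ** 2
    out[~small] = 2 * np.pi * const.R_E_CM**2 * (t1 + t2 - t3)
    return out if out.size > 1 else float(out[0])


def _screened_form_factor(s, Z: int):
    """Atomic form factor f0(s), s = sin(theta/2)/lambda in 1/Angstrom.

    Exponential-screening approximation f0 = Z (1+(s/s0)^2)^(-3/2) with
    s0 = 0.2014 Z^(1/3), normalized against the Cromer-Mann carbon factor.
    """
    s0 = 0.2014 * Z ** (1.0 / 3.0)
    return Z * (1.0 + (np.asarray(s) / s0) ** 2) ** (-1.5)


def carbon_form_factor(s):
    """Cromer-Mann carbon form factor f0(s), s = sin(theta)/lambda in 1/A."""
    s2 = np.asarray(s, dtype=float) ** 2
    f = CARBON_CROMER_MANN_C + sum(
        a * np.exp(-b * s2) for a, b in zip(CARBON_CROMER_MANN_A, CARBON_CROMER_MANN_B)
    )
    return float(f) if np.isscalar(s) else f


_COH_GRID = np.geomspace(1.0, 200.0, 40)
_COH_CACHE: dict[str, np.ndarray] = {}
_COH_THETA = np.linspace(0.0, np.pi, 2001)


def _coherent_sigma_per_gram(symbol: str) -> np.ndarray:
    """sigma_coh/rho (cm^2/g) on _COH_GRID, cached per element."""
    if symbol in _COH_CACHE:
        return _COH_CACHE[symbol]
    Z, A = ELEMENT_PROPS[symbol]
    theta = _COH_THETA
    geom = 0.5 * (1 + np.cos(theta) ** 2) * np.sin(theta)  # Thomson x Jacobian
    lam = const.HC_KEV_ANGSTROM / _COH_GRID  # (n_E,)
    s = np.sin(theta / 2)[None, :] / lam[:, None]  # (n_E, n_theta)
    # the screened factor decays ~s^-3 at large momentum transfer, unlike the
    # Cromer-Mann fit whose constant term is unphysical beyond its fit range
    ff = _screened_form_factor(s, Z)
    integrand = geom[None, :] * ff**2
    sigma_atom = 2 * np.pi * const.R_E_CM**2 * np.trapezoid(integrand, theta, axis=1)
    out = sigma_atom * const.N_AVOGADRO / A
    _COH_CACHE[symbol] = out
    return out


def _loglog_interp(x, xp, fp):
    return np.exp(np.interp(np.log(x), np.log(xp), np.log(np.maximum(fp, 1e-300))))


_COMPONENTS = ("photoelectric", "compton", "rayleigh", "total", "transport_total")


def element_mass_attenuation(symbol: str, energy_kev, component: str = "transport_total"):
    """Mass attenuation coefficient mu/rho (cm^2/g) of a single element."""
    if symbol not in ELEMENT_PROPS:
        raise KeyError(f"unknown element {symbol!r}")
    if component not in _COMPONENTS:
        raise ValueError(f"component must be one of {_COMPONENTS}")
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    if np.any((e < 1.0) | (e > 200.0)):
        raise ValueError("energy outside the tabulated 1-200 keV range")
    Z, A = ELEMENT_PROPS[symbol]
    out = np.zeros_like(e)
    if component in ("photoelectric", "total", "transport_total"):
        ep, vp = PE_TABLES[symbol]
        out += _loglog_interp(e, ep, vp)
    if component in ("compton", "total", "transport_total"):
        out += klein_nishina_total_cm2(e) * const.N_AVOGADRO * Z / A
    if component in ("rayleigh", "transport_total"):
        out += _loglog_interp(e, _COH_GRID, _coherent_sigma_per_gram(symbol))
    return out if out.size > 1 else float(out[0])


def mass_attenuation(material: MaterialSpec, energy_kev, component: str = "total"):
    """Mixture-rule mu/rho (cm^2/g) for a material.

    ``component='total'`` is photoelectric + Compton (the reflectivity-formula
    convention); use ``'transport_total'`` for path sampling.
    """
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    out = np.zeros_like(e)
    for sym, frac in material.composition:
        out += frac * np.atleast_1d(element_mass_attenuation(sym, e, component))
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Fluorescence
# ---------------------------------------------------------------------------

def fluorescence_lines(element: str) -> list[FluorescenceLine]:
    """K-series lines of an element, probabilities normalized within the series."""
    if element not in K_FLUORESCENCE:
        raise KeyError(
            f"no fluorescence data for {element!r}; supported: "
            f"{sorted(K_FLUORESCENCE)}"
        )
    omega, rows = K_FLUORESCENCE[element]
    total = sum(w for _, _, w in rows)
    return [
        FluorescenceLine(element, label, energy, w / total, omega)
        for label, energy, w in rows
    ]


# ---------------------------------------------------------------------------
# Materials registry
# ---------------------------------------------------------------------------

def _mat(name, comp, density):
    return MaterialSpec(name=name, composition=tuple(comp), density=density)


def _normalized(comp):
    total = sum(f for _, f in comp)
    return [(s, f / total) for s, f in comp]


MATERIALS: dict[str, MaterialSpec] = {}


def register_material(mat: MaterialSpec) -> None:
    MATERIALS[mat.name] = mat


def get_material(name: str) -> MaterialSpec:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(MATERIALS)}"
        ) from None


for _m in [
    _mat("graphite", [("C", 1.0)], 2.26),  # ideal HOPG density; configurable
    _mat("aluminum", [("Al", 1.0)], 2.699),
    _mat("lead", [("Pb", 1.0)], 11.35),
    _mat("hafnium", [("Hf", 1.0)], 13.31),
    _mat("tungsten", [("W", 1.0)], 19.30),
    _mat("silicon", [("Si", 1.0)], 2.33),
    _mat("water", [("H", 0.111894), ("O", 0.888106)], 1.0),
    _mat("cdte", _normalized([("Cd", 112.41), ("Te", 127.60)]), 5.85),
    _mat("glass_sio2", _normalized([("Si", 28.085), ("O", 2 * 15.999)]), 2.2),
    _mat("acrylic", [("H", 0.080538), ("C", 0.599848), ("O", 0.319614)], 1.19),
    # ICRP soft/adipose tissue; sub-0.02% trace metals dropped and the
    # remainder renormalized.  Densities per the package convention.
    _mat(
        "soft_tissue",
        _normalized([
            ("H", 0.104472), ("C", 0.232190), ("N", 0.024880), ("O", 0.630238),
            ("Na", 0.001130), ("P", 0.001330), ("S", 0.001990),
            ("Cl", 0.001340), ("K", 0.001990), ("Ca", 0.000230),
        ]),
        1.06,
    ),
    _mat(
        "adipose",
        _normalized([
            ("H", 0.114), ("C", 0.598), ("N", 0.007), ("O", 0.278),
            ("Na", 0.001), ("S", 0.001), ("Cl", 0.001),
        ]),
        0.95,
    ),
]:
    register_material(_m)


def load_materials_yaml(path) -> list[MaterialSpec]:
    """Load/override materials from a YAML file.

    Expected layout::

        materials:
          my_tissue:
            density: 1.05
            composition: {H: 0.10, C: 0.20, O: 0.70}

    Compositions are renormalized to sum exactly to one.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    loaded = []
    for name, entry in (doc.get("materials") or {}).items():
        comp = _normalized(list(entry["composition"].items()))
        mat = _mat(name, comp, float(entry["density"]))
        register_material(mat)
        loaded.append(mat)
    return loaded
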