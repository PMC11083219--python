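"""Monte Carlo photon transport.

Analog photon tracking with exponential free paths.  Interaction channels
are photoelectric absorption (with single K-vacancy fluorescence emission),
free-electron Klein-Nishina Compton scattering and coherent (Rayleigh)
scattering from screened atomic form factors.  Inside mosaic-crystal volumes
the Rayleigh channel is replaced by the Bragg-diffraction channel: at every
candidate interaction a virtual crystallite orientation is drawn from the
truncated Lorentzian mosaic distribution, the diffraction coefficient is
evaluated at the Bragg mismatch to that crystallite, and -- when the channel
fires -- the photon reflects specularly about the sampled crystallite
normal.  Multiple diffraction events per history are allowed.  The crystal
walk is implemented with Woodcock (null-collision) tracking under the
majorant Q W(0;m).

Energy is deposited locally at interaction sites (kerma approximation: no
secondary-electron transport, adequate below 150 keV on sub-millimeter
scales).  Lengths are mm; attenuation coefficients are converted from
cm^2/g internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as const
from .mosaic_crystal import (
    MosaicCrystalSpec,
    bragg_angle_rad,
    kinematical_Q,
    mosaic_pdf,
    sample_crystallite_tilts,
)
from .xray_data import (
    MaterialSpec,
    K_EDGE_KEV,
    element_mass_attenuation,
    fluorescence_lines,
    get_material,
    mass_attenuation,
)
from ._attenuation_tables import ELEMENT_PROPS, K_FLUORESCENCE

__all__ = [
    "Photon",
    "InteractionRecord",
    "compton_scatter",
    "sample_compton",
    "sample_rayleigh_mu",
    "photoelectric_absorb",
    "bragg_reflect",
    "CrystalSlabResult",
    "transport_crystal_slab",
    "transport_homogeneous_slab",
    "rotate_directions",
]

_MAX_STEPS = 10_000


@dataclass
class Photon:
    """A tracked particle: energy (keV), position (mm), unit direction."""

    energy: float
    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    alive: bool = True
    history_id: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)


@dataclass(frozen=True)
class InteractionRecord:
    position: tuple
    process: str  # diffraction|photoelectric|compton|rayleigh|fluorescence-emission|escape
    energy_deposited: float
    solid_id: str = ""


# ---------------------------------------------------------------------------
# Interaction sampling
# ---------------------------------------------------------------------------

def compton_energy_after(energy_kev, theta_rad):
    """Compton formula E' = E / (1 + (E/m_e c^2)(1 - cos theta))."""
    e = np.asarray(energy_kev, dtype=float)
    return e / (1.0 + (e / const.ELECTRON_REST_KEV) * (1.0 - np.cos(theta_rad)))


def sample_compton(energies, rng: np.random.Generator):
    """Sample Klein-Nishina scattering for an array of photon energies.

    Returns (scattered energies, polar angles).  Uses the standard two-branch
    composition-rejection method on eps = E'/E.
    """
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    n = len(e)
    alpha = e / const.ELECTRON_REST_KEV
    eps0 = 1.0 / (1.0 + 2.0 * alpha)
    a1 = np.log(1.0 / eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    eps = np.empty(n)
    one_minus_cos = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        m = len(todo)
        if m == 0:
            break
        u1, u2, u3 = rng.random(m), rng.random(m), rng.random(m)
        use_log = u1 < a1[todo] / (a1[todo] + a2[todo])
        cand = np.where(
            use_log,
            eps0[todo] ** u2,
            np.sqrt(eps0[todo] ** 2 + (1.0 - eps0[todo] ** 2) * u2),
        )
        t = (1.0 - cand) / (alpha[todo] * cand)
        sin2 = t * (2.0 - t)
        g = 1.0 - cand * sin2 / (1.0 + cand**2)
        ok = u3 <= g
        sel = todo[ok]
        eps[sel] = cand[ok]
        one_minus_cos[sel] = t[ok]
        todo = todo[~ok]
    else:  # pragma: no cover - rejection loop essentially always terminates
        raise RuntimeError("Compton sampling failed to converge")
    cos_t = np.clip(1.0 - one_minus_cos, -1.0, 1.0)
    return e * eps, np.arccos(cos_t)


def compton_scatter(energy_kev: float, rng: np.random.Generator):
    """Single-photon convenience wrapper: returns (E', polar angle rad)."""
    e2, th = sample_compton(np.array([energy_kev]), rng)
    return float(e2[0]), float(th[0])


def sample_rayleigh_mu(energies, Z, rng: np.random.Generator):
    """Sample cos(theta) for coherent scattering off element Z.

    Momentum transfer is drawn from the screened form-factor density
    (analytically invertible), then the Thomson polarization factor is
    applied by rejection.
    """
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    lam = const.HC_KEV_ANGSTROM / e
    s0 = 0.2014 * np.asarray(Z, dtype=float) ** (1.0 / 3.0)
    s0 = np.broadcast_to(np.atleast_1d(s0), e.shape)
    x_max = 1.0 / lam**2  # s^2 at theta = pi
    n = len(e)
    mu = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        m = len(todo)
        if m == 0:
            break
        u1, u2 = rng.random(m), rng.random(m)
        s2_0 = s0[todo] ** 2
        # CDF of p(x) ~ (1+x/s2_0)^-3 truncated at x_max
        cmax = 1.0 - (1.0 + x_max[todo] / s2_0) ** -2
        x = s2_0 * ((1.0 - u1 * cmax) ** -0.5 - 1.0)
        c = 1.0 - 2.0 * lam[todo] ** 2 * x
        ok = u2 <= 0.5 * (1.0 + c**2)
        sel = todo[ok]
        mu[sel] = np.clip(c[ok], -1.0, 1.0)
        todo = todo[~ok]
    else:  # pragma: no cover
        raise RuntimeError("Rayleigh sampling failed to converge")
    return mu


def photoelectric_absorb(energy_kev: float, element: str, rng: np.random.Generator):
    """Resolve a photoelectric event in ``element``.

    Returns (fluorescence photon energy or None, locally deposited energy).
    A K fluorescence photon is emitted with probability omega_K when the
    photon energy exceeds the K edge; sub-K vacancies deposit locally.
    """
    edge = K_EDGE_KEV.get(element)
    if edge is None or energy_kev < edge or element not in K_FLUORESCENCE:
        return None, energy_kev
    lines = fluorescence_lines(element)
    if rng.random() >= lines[0].omega_k:
        return None, energy_kev
    probs = np.array([ln.probability for ln in lines])
    idx = rng.choice(len(lines), p=probs)
    e_fl = lines[idx].energy
    return e_fl, energy_kev - e_fl


def rotate_directions(directions, polar, azimuth):
    """Rotate unit vectors by polar angle about themselves with given azimuth."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    th = np.atleast_1d(np.asarray(polar, dtype=float))
    ph = np.atleast_1d(np.asarray(azimuth, dtype=float))
    helper = np.zeros_like(d)
    small_x = np.abs(d[:, 0]) < 0.9
    helper[small_x, 0] = 1.0
    helper[~small_x, 1] = 1.0
    t1 = np.cross(d, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(d, t1)
    st = np.sin(th)[:, None]
    out = (
        np.cos(th)[:, None] * d
        + st * np.cos(ph)[:, None] * t1
        + st * np.sin(ph)[:, None] * t2
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def bragg_reflect(direction, crystallite_normal):
    """Specular reflection of the photon direction about a crystallite normal.

    Elastic: the energy is untouched; only the direction changes.
    """
    d = np.asarray(direction, dtype=float)
    g = np.asarray(crystallite_normal, dtype=float)
    dn = np.sum(d * g, axis=-1, keepdims=True)
    return d - 2.0 * dn * g


# ---------------------------------------------------------------------------
# Crystal-slab engine
# ---------------------------------------------------------------------------

@dataclass
class CrystalSlabResult:
    """Exit inventory of a crystal-slab transport run (slab frame: the
    entrance face is z = 0 with vacuum above, the substrate below z = -T)."""

    position: np.ndarray       # (n, 3) final positions, mm
    direction: np.ndarray      # (n, 3)
    energy: np.ndarray         # (n,)
    weight: np.ndarray         # (n,)
    escaped_up: np.ndarray     # bool: re-emerged through the entrance face
    into_substrate: np.ndarray # bool: left through the back face
    absorbed: np.ndarray       # bool: terminated inside the crystal
    n_diffractions: np.ndarray # int per history
    deposited: np.ndarray      # keV per history (inside the crystal layer)


def transport_crystal_slab(
    energies,
    positions,
    directions,
    spec: MosaicCrystalSpec,
    rng: np.random.Generator,
    crystal_material: MaterialSpec | None = None,
    weights=None,
    cutoff_kev: float = const.ENERGY_CUTOFF_KEV,
    max_steps: int = 500,
) -> CrystalSlabResult:
    """Track photons through a planar mosaic-crystal layer.

    Photons must start on or above the entrance face (z >= 0 moving down, or
    inside the layer).  The substrate is treated as an absorber: histories
    crossing the back face are terminated there (their state is recorded).
    This is the engine behind both the rocking-curve experiment and the
    local-slab treatment of the thin bent crystal on the ellipsoid.
    """
    if crystal_material is None:
        crystal_material = get_material("graphite")
    e = np.array(energies, dtype=float, copy=True)
    pos = np.array(positions, dtype=float, copy=True)
    d = np.array(directions, dtype=float, copy=True)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    n = len(e)
    w = np.ones(n) if weights is None else np.array(weights, dtype=float, copy=True)

    thickness_mm = spec.thickness_um * 1e-3
    rho = crystal_material.density
    # per-mm coefficients at each photon energy
    mu_pe = element_mass_attenuation("C", e, "photoelectric") * rho * 0.1
    mu_co = element_mass_attenuation("C", e, "compton") * rho * 0.1
    q_mm = np.asarray(kinematical_Q(e, spec)) * 0.1
    w0 = mosaic_pdf(0.0, spec.mosaic_fwhm_rad)
    theta_b = np.asarray(bragg_angle_rad(e, spec))

    mu_pe = np.atleast_1d(mu_pe)
    mu_co = np.atleast_1d(mu_co)
    q_mm = np.atleast_1d(q_mm)
    theta_b = np.atleast_1d(theta_b)

    alive = np.ones(n, dtype=bool)
    escaped_up = np.zeros(n, dtype=bool)
    into_substrate = np.zeros(n, dtype=bool)
    absorbed = np.zeros(n, dtype=bool)
    n_diff = np.zeros(n, dtype=np.int64)
    deposited = np.zeros(n)

    # advance photons starting above the surface onto it
    above = pos[:, 2] > 0
    if np.any(above):
        going_down = d[above, 2] < 0
        t_surf = np.where(going_down, -pos[above, 2] / np.where(d[above, 2] == 0, -1, d[above, 2]), np.inf)
        miss = ~np.isfinite(t_surf)
        pos[above] += np.where(np.isfinite(t_surf), t_surf, 0.0)[:, None] * d[above]
        idx_above = np.flatnonzero(above)
        esc = idx_above[miss]
        escaped_up[esc] = True
        alive[esc] = False
        pos[:, 2] = np.minimum(pos[:, 2], 0.0)

    for _ in range(max_steps):
        act = np.flatnonzero(alive)
        if len(act) == 0:
            break
        mu_maj = mu_pe[act] + mu_co[act] + q_mm[act] * w0
        step = -np.log(rng.random(len(act))) / mu_maj
        new_pos = pos[act] + step[:, None] * d[act]
        z = new_pos[:, 2]

        out_top = z > 0.0
        out_bot = z < -thickness_mm
        # move boundary-crossers exactly to the face they crossed
        dz = d[act, 2]
        t_top = np.where(dz > 0, (0.0 - pos[act, 2]) / np.where(dz == 0, 1, dz), np.inf)
        t_bot = np.where(dz < 0, (-thickness_mm - pos[act, 2]) / np.where(dz == 0, 1, dz), np.inf)
        cross_top = out_top & (t_top <= step)
        cross_bot = out_bot & (t_bot <= step)
        idx_top = act[cross_top]
        idx_bot = act[cross_bot]
        pos[idx_top] += t_top[cross_top][:, None] * d[idx_top]
        pos[idx_bot] += t_bot[cross_bot][:, None] * d[idx_bot]
        escaped_up[idx_top] = True
        into_substrate[idx_bot] = True
        alive[idx_top] = False
        alive[idx_bot] = False

        inside = ~(cross_top | cross_bot)
        col = act[inside]
        if len(col) == 0:
            continue
        pos[col] = new_pos[inside]

        # virtual crystallite per collision candidate
        m = len(col)
        a1 = sample_crystallite_tilts(spec.mosaic_fwhm_rad, m, rng, spec.truncation)
        a2 = sample_crystallite_tilts(spec.mosaic_fwhm_rad, m, rng, spec.truncation)
        g = np.column_stack([np.tan(a1), np.tan(a2), np.ones(m)])
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        sin_inc = np.abs(np.einsum("ij,ij->i", d[col], g))
        delta = np.arcsin(np.clip(sin_inc, 0, 1)) - theta_b[col]
        mu_diff = q_mm[col] * mosaic_pdf(delta, spec.mosaic_fwhm_rad)

        mu_m = mu_maj[inside]
        u = rng.random(m) * mu_m
        p_pe = mu_pe[col]
        p_co = p_pe + mu_co[col]
        p_df = p_co + mu_diff

        is_pe = u < p_pe
        is_co = (u >= p_pe) & (u < p_co)
        is_df = (u >= p_co) & (u < p_df)
        # else: null collision, photon continues unchanged

        if np.any(is_pe):
            idx = col[is_pe]
            deposited[idx] += e[idx]  # carbon: no K fluorescence above 1 keV cutoff
            absorbed[idx] = True
            alive[idx] = False
        if np.any(is_co):
            idx = col[is_co]
            e_new, theta = sample_compton(e[idx], rng)
            deposited[idx] += e[idx] - e_new
            phi = rng.uniform(0, 2 * np.pi, len(idx))
            d[idx] = rotate_directions(d[idx], theta, phi)
            e[idx] = e_new
            # coefficient update at the new energy
            mu_pe[idx] = element_mass_attenuation("C", e_new, "photoelectric") * rho * 0.1
            mu_co[idx] = element_mass_attenuation("C", e_new, "compton") * rho * 0.1
            below = e_new < max(cutoff_kev, 1.0)
            die = idx[below]
            deposited[die] += e[die]
            absorbed[die] = True
            alive[die] = False
            ok = idx[~below]
            q_mm[ok] = np.asarray(kinematical_Q(e[ok], spec)) * 0.1
            theta_b[ok] = np.asarray(bragg_angle_rad(e[ok], spec))
        if np.any(is_df):
            idx = col[is_df]
            d[idx] = bragg_reflect(d[idx], g[is_df])
            n_diff[idx] += 1
    else:
        # stuck-photon guard: kill whatever is left and record as absorbed
        still = np.flatnonzero(alive)
        deposited[still] += e[still]
        absorbed[still] = True
        alive[still] = False

    return CrystalSlabResult(
        position=pos, direction=d, energy=e, weight=w,
        escaped_up=escaped_up, into_substrate=into_substrate, absorbed=absorbed,
        n_diffractions=n_diff, deposited=deposited,
    )


# ---------------------------------------------------------------------------
# Homogeneous-slab engine (no crystal): Beer-Lambert / bookkeeping oracle
# ---------------------------------------------------------------------------

def transport_homogeneous_slab(
    energies,
    material: MaterialSpec,
    thickness_mm: float,
    rng: np.random.Generator,
    cutoff_kev: float = const.ENERGY_CUTOFF_KEV,
    max_steps: int = 200,
):
    """Track a pencil beam (along +z) through a homogeneous slab.

    Full analog physics: photoelectric (with K fluorescence where defined),
    Compton, Rayleigh.  Returns a dict with per-history accounting:
    ``transmitted_unscattered`` (bool), ``escaped_energy``, ``deposited``,
    ``n_interactions``.  Energy is conserved per history to rounding.
    """
    e = np.array(energies, dtype=float, copy=True)
    n = len(e)
    pos = np.zeros((n, 3))
    d = np.tile([0.0, 0.0, 1.0], (n, 1))
    alive = np.ones(n, dtype=bool)
    deposited = np.zeros(n)
    escaped_energy = np.zeros(n)
    n_inter = np.zeros(n, dtype=np.int64)

    elements = [s for s, _ in material.composition]
    fracs = np.array([f for _, f in material.composition])

    def mu_parts(en):
        pe = np.zeros_like(en)
        per_el_pe = []
        for sym, f in material.composition:
            v = f * np.atleast_1d(element_mass_attenuation(sym, en, "photoelectric"))
            per_el_pe.append(v)
            pe += v
        co = np.atleast_1d(mass_attenuation(material, en, "compton"))
        ra = np.atleast_1d(mass_attenuation(material, en, "rayleigh"))
        rho01 = material.density * 0.1
        return pe * rho01, co * rho01, ra * rho01, [v * rho01 for v in per_el_pe]

    for _ in range(max_steps):
        act = np.flatnonzero(alive)
        if len(act) == 0:
            break
        mu_pe, mu_co, mu_ra, per_el = mu_parts(e[act])
        mu_tot = mu_pe + mu_co + mu_ra
        step = -np.log(rng.random(len(act))) / mu_tot
        newp = pos[act] + step[:, None] * d[act]
        out = (newp[:, 2] < 0.0) | (newp[:, 2] > thickness_mm)
        idx_out = act[out]
        escaped_energy[idx_out] += e[idx_out]
        alive[idx_out] = False
        col = act[~out]
        if len(col) == 0:
            continue
        pos[col] = newp[~out]
        n_inter[col] += 1
        sub = ~out
        u = rng.random(len(col)) * mu_tot[sub]
        is_pe = u < mu_pe[sub]
        is_co = (u >= mu_pe[sub]) & (u < mu_pe[sub] + mu_co[sub])
        is_ra = ~(is_pe | is_co)

        if np.any(is_pe):
            idx = col[is_pe]
            # element choice proportional to its photoelectric share
            stack = np.column_stack([v[sub][is_pe] for v in per_el])
            cdf = np.cumsum(stack, axis=1)
            pick = (rng.random(len(idx))[:, None] * cdf[:, -1:] < cdf).argmax(axis=1)
            for j, (ph_idx, el_i) in enumerate(zip(idx, pick)):
                e_fl, dep = photoelectric_absorb(e[ph_idx], elements[el_i], rng)
                deposited[ph_idx] += dep
                if e_fl is not None and e_fl >= cutoff_kev:
                    # isotropic re-emission, same history continues as the
                    # fluorescence photon
                    mu_iso = rng.uniform(-1, 1)
                    phi = rng.uniform(0, 2 * np.pi)
                    s_iso = math.sqrt(1 - mu_iso**2)
                    d[ph_idx] = [s_iso * math.cos(phi), s_iso * math.sin(phi), mu_iso]
                    e[ph_idx] = e_fl
                else:
                    if e_fl is not None:
                        deposited[ph_idx] += e_fl
                    alive[ph_idx] = False
        if np.any(is_co):
            idx = col[is_co]
            e_new, theta = sample_compton(e[idx], rng)
            deposited[idx] += e[idx] - e_new
            phi = rng.uniform(0, 2 * np.pi, len(idx))
            d[idx] = rotate_directions(d[idx], theta, phi)
            e[idx] = e_new
            below = e_new < cutoff_kev
            die = idx[below]
            deposited[die] += e[die]
            alive[die] = False
        if np.any(is_ra):
            idx = col[is_ra]
            # effective Z: coherent scattering off a fraction-weighted element
            zpick = rng.choice(len(elements), size=len(idx), p=fracs)
            zs = np.array([ELEMENT_PROPS[elements[k]][0] for k in zpick])
            mu_sc = sample_rayleigh_mu(e[idx], zs, rng)
            phi = rng.uniform(0, 2 * np.pi, len(idx))
            d[idx] = rotate_directions(d[idx], np.arccos(mu_sc), phi)

    return {
        "energy": e,
        "deposited": deposited,
        "escaped_energy": escaped_energy,
        "transmitted_unscattered": (~alive) & (n_inter == 0) & (escaped_energy > 0),
        "n_interactions": n_inter,
    }
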