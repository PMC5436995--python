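"""Unit-density sphere self-dose model and cylindrical mass estimation.

Used for structures that are not part of the reference phantoms (here the
choroid plexuses of the lateral brain ventricles): the structure is modelled
as a unit-density sphere of the measured mass, and the self-dose S value is

    S = [ Delta_np * phi_np(m) + sum_i y_i E_i * phi_gamma(m, E_i) ] / m

where ``Delta_np`` is the mean non-penetrating (beta+/Auger) energy emitted
per decay, ``phi_np`` the electron absorbed fraction and ``phi_gamma`` the
photon self-absorption fraction.

The electron absorbed fraction is computed geometrically: positrons are
treated as straight tracks of length equal to their CSDA range in water,
depositing energy uniformly along the track, emitted isotropically from a
uniformly distributed source inside the sphere.  The fraction is averaged
over the allowed beta+ spectrum of each branch (energy weighted), so that
the short-range low-energy part of the spectrum is fully absorbed while the
energetic tail partially escapes small spheres.  Any non-beta,
non-penetrating remainder of ``Delta_np`` (Auger and conversion electrons)
is taken as locally absorbed.  phi_np -> 1 for masses much larger than the
beta range and < 1 for masses of a few grams, as required.

Photon self-absorption uses the mean escape path of a uniform spherical
source (3R/4) with mass energy-absorption coefficients of water,
``phi_gamma = 1 - exp(-mu_en * 3R/4)``; it is a few percent for gram-sized
spheres and matters only for large masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import MEV_PER_DECAY_TO_MGY, UNIT_DENSITY

__all__ = [
    "SphereTarget",
    "CylinderPart",
    "cylinder_mass",
    "sphere_self_svalue",
    "sphere_dose",
    "electron_absorbed_fraction",
    "photon_absorbed_fraction",
    "csda_range_water",
    "beta_spectrum",
]

#: supported mass range of the sphere model, g
MASS_RANGE_G = (0.01, 6000.0)

# CSDA range of electrons in water, from a standard stopping-power
# compilation: (energy MeV, range g/cm^2); log-log interpolated.
_CSDA_E_MEV = np.array(
    [0.01, 0.02, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.70, 1.00, 1.25, 1.50, 2.00, 2.50, 3.00]
)
_CSDA_R_GCM2 = np.array(
    [
        2.515e-4, 8.566e-4, 4.320e-3, 1.431e-2, 4.479e-2, 8.371e-2, 1.280e-1,
        1.766e-1, 2.795e-1, 4.367e-1, 5.686e-1, 7.075e-1, 9.785e-1, 1.2605, 1.514,
    ]
)

# Mass energy-absorption coefficient of water, cm^2/g, log-log interpolated.
_MUEN_E_MEV = np.array([0.10, 0.20, 0.30, 0.50, 0.60, 0.80, 1.00, 1.25, 1.50, 2.00])
_MUEN_CM2G = np.array(
    [0.02546, 0.02967, 0.03192, 0.03299, 0.03284, 0.03206, 0.03103, 0.02965, 0.02833, 0.02608]
)

_ELECTRON_MASS_MEV = 0.51099895


def csda_range_water(energy_mev: float | np.ndarray) -> np.ndarray:
    """CSDA range (cm, unit density) of electrons/positrons in water."""
    e = np.clip(np.asarray(energy_mev, dtype=float), _CSDA_E_MEV[0], _CSDA_E_MEV[-1])
    return np.exp(np.interp(np.log(e), np.log(_CSDA_E_MEV), np.log(_CSDA_R_GCM2)))


def _muen_water(energy_mev: float) -> float:
    e = min(max(float(energy_mev), _MUEN_E_MEV[0]), _MUEN_E_MEV[-1])
    return float(np.exp(np.interp(math.log(e), np.log(_MUEN_E_MEV), np.log(_MUEN_CM2G))))


def beta_spectrum(e_max_mev: float, n: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Allowed-shape beta spectrum on a uniform energy grid.

    Returns (energies MeV, unnormalised density). The Coulomb (Fermi)
    correction is omitted; for the purpose of an energy-weighted absorbed
    fraction this changes the result well below the model's own accuracy.
    """
    if e_max_mev <= 0:
        raise ValueError("e_max_mev must be positive")
    e = np.linspace(e_max_mev / (2 * n), e_max_mev * (1 - 1.0 / (2 * n)), n)
    w = e / _ELECTRON_MASS_MEV + 1.0
    w0 = e_max_mev / _ELECTRON_MASS_MEV + 1.0
    p = np.sqrt(w**2 - 1.0)
    return e, p * w * (w0 - w) ** 2


def _geometric_fraction(radius_cm: float, track_cm: np.ndarray) -> np.ndarray:
    """Fraction of a straight track of given length deposited inside a sphere.

    Emission points are uniform in the sphere, directions isotropic, energy
    deposited uniformly along the track: phi = E[min(d, L)] / L where d is
    the distance from the emission point to the surface.  Evaluated by
    Gauss-Legendre quadrature over radius and direction cosine.
    """
    r_nodes, r_weights = np.polynomial.legendre.leggauss(48)
    c_nodes, c_weights = np.polynomial.legendre.leggauss(48)
    # radius: pdf 3 r^2 / R^3 on (0, R)
    r = 0.5 * radius_cm * (r_nodes + 1.0)
    wr = 0.5 * radius_cm * r_weights * 3.0 * r**2 / radius_cm**3
    c = c_nodes  # direction cosine, uniform on (-1, 1)
    wc = 0.5 * c_weights
    rr, cc = np.meshgrid(r, c, indexing="ij")
    d = -rr * cc + np.sqrt(radius_cm**2 - rr**2 * (1.0 - cc**2))
    ww = np.outer(wr, wc)
    track = np.asarray(track_cm, dtype=float)
    out = np.empty(track.shape)
    for i, length in np.ndenumerate(track):
        if length <= 0:
            out[i] = 1.0
        else:
            out[i] = np.sum(ww * np.minimum(d, length)) / length
    return out


def electron_absorbed_fraction(mass_g: float, beta_branches, density: float = UNIT_DENSITY) -> float:
    """Energy-weighted electron absorbed fraction for a unit-density sphere.

    ``beta_branches`` is a list of (yield per decay, endpoint energy MeV).
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    radius = (3.0 * mass_g / density / (4.0 * math.pi)) ** (1.0 / 3.0)
    num = 0.0
    den = 0.0
    for branch_yield, e_max in beta_branches:
        e, dens = beta_spectrum(e_max)
        phi = _geometric_fraction(radius, csda_range_water(e))
        num += branch_yield * float(np.sum(dens * e * phi)) / float(np.sum(dens))
        den += branch_yield * float(np.sum(dens * e)) / float(np.sum(dens))
    if den == 0.0:
        return 1.0
    return num / den


def photon_absorbed_fraction(mass_g: float, energy_mev: float, density: float = UNIT_DENSITY) -> float:
    """Photon self-absorption fraction of a unit-density sphere."""
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    radius = (3.0 * mass_g / density / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 1.0 - math.exp(-_muen_water(energy_mev) * 0.75 * radius * density)


@dataclass(frozen=True)
class SphereTarget:
    """A non-phantom structure dosed with the unit-density sphere model."""

    name: str
    mass_g: float
    density: float = UNIT_DENSITY

    def __post_init__(self):
        if self.mass_g <= 0:
            raise ValueError("sphere mass must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class CylinderPart:
    """One cylindrical segment of a structure, dimensions in mm."""

    label: str
    length_mm: float
    width_mm: float

    def __post_init__(self):
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("cylinder dimensions must be positive")


def cylinder_mass(parts, density: float = UNIT_DENSITY, bilateral: bool = False) -> float:
    """Mass (g) of a set of cylindrical parts, doubled for bilateral structures."""
    parts = list(parts)
    if not parts:
        raise ValueError("at least one cylinder part is required")
    volume_cm3 = sum(math.pi * (p.width_mm / 20.0) ** 2 * (p.length_mm / 10.0) for p in parts)
    mass = density * volume_cm3
    return 2.0 * mass if bilateral else mass


def sphere_self_svalue(target: SphereTarget, nuclide) -> float:
    """Self-dose S value of a unit-density sphere, mGy/(MBq.h)."""
    if not (MASS_RANGE_G[0] <= target.mass_g <= MASS_RANGE_G[1]):
        raise ValueError(
            f"sphere mass {target.mass_g} g outside supported range {MASS_RANGE_G}"
        )
    return _unchecked_self_svalue(target.mass_g, nuclide, target.density)


def _unchecked_self_svalue(mass_g: float, nuclide, density: float = UNIT_DENSITY) -> float:
    """Self S value without the public-range guard (used by fixture generation)."""
    phi_np = electron_absorbed_fraction(mass_g, nuclide.beta_plus_branches, density)
    # the non-beta part of delta_np (Auger/conversion electrons) is locally absorbed
    delta_beta = sum(
        y * _mean_beta_energy(e_max) for y, e_max in nuclide.beta_plus_branches
    )
    delta_auger = max(nuclide.delta_np_mev - delta_beta, 0.0)
    energy = delta_beta * phi_np + delta_auger
    for branch_yield, e_gamma in nuclide.photon_lines:
        energy += branch_yield * e_gamma * photon_absorbed_fraction(mass_g, e_gamma, density)
    return energy * MEV_PER_DECAY_TO_MGY / mass_g


def _mean_beta_energy(e_max_mev: float) -> float:
    e, dens = beta_spectrum(e_max_mev)
    return float(np.sum(dens * e) / np.sum(dens))


def sphere_dose(target: SphereTarget, tau_h: float, nuclide) -> float:
    """Absorbed dose (mGy/MBq) to a sphere target with residence time ``tau_h``."""
    if tau_h < 0:
        raise ValueError("residence time must be non-negative")
    return tau_h * sphere_self_svalue(target, nuclide)
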