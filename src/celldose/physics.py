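"""Nuclear constants, two-body reaction kinematics and charged-particle stopping.

This module carries the physics shared by every other part of the package:

* the ``¹⁰B(n,α)⁷Li`` capture channels (6% ground-state branch, 94% excited
  branch followed by a 478 keV photon) and the ``p + ¹¹B → 3α`` fusion channel
  with its ~1 barn resonance near 675 keV proton energy;
* non-relativistic two-body kinematics for a capture at rest;
* the α-yield formula ``Y = σ_R · n_B`` (reactions per incident proton for an
  areal density ``n_B`` in atoms/barn);
* a Bethe stopping-power model for protons and α particles in water, air,
  Mylar and elemental boron, with a power-law continuation below the Bethe
  validity limit and CSDA ranges by adaptive quadrature.

Units are fixed package-wide: MeV, barn, µm, g/cm³.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import EnergyRangeError, InvalidArgumentError

# --- fundamental constants -------------------------------------------------

K_BETHE = 0.307075          # MeV cm^2 / mol  (4*pi*N_A*r_e^2*m_e*c^2)
ME_C2 = 0.51099895          # MeV, electron rest energy
PROTON_MASS_MEV = 938.27208816
ALPHA_MASS_MEV = 3727.3794
AVOGADRO = 6.02214076e23
MEV_TO_J = 1.602176634e-13
BARN_TO_CM2 = 1.0e-24
CM_PER_UM = 1.0e-4

# atomic data: symbol -> (Z, standard atomic weight)
_ELEMENTS = {
    "H": (1, 1.008),
    "B": (5, 10.811),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Ar": (18, 39.948),
    "Fe": (26, 55.845),
}

A_B10 = 10.013
A_B11 = 11.009
F_B10 = 0.199   # natural-abundance fraction of the neutron-active isotope
F_B11 = 0.801

# Bethe validity limit, expressed as the kinetic energy of a PROTON; particles
# of other species are mapped to the proton curve at equal velocity.
_E_JUNCTION_MEV = 0.5
_E_MIN_MEV = 1.0e-3
_E_MAX_MEV = 20.0


# --- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class Nuclide:
    symbol: str
    mass_number: int
    charge: int
    natural_abundance_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_number < 1:
            raise InvalidArgumentError("mass_number must be >= 1")
        if not 0.0 <= self.natural_abundance_fraction <= 1.0:
            raise InvalidArgumentError("abundance must lie in [0, 1]")


@dataclass(frozen=True)
class ReactionChannel:
    """One decay channel of a two-body capture or fusion reaction."""

    reactants: tuple[Nuclide, Nuclide]
    products: tuple[tuple[Nuclide, str], ...]
    branching_fraction: float
    kinetic_release: float          # MeV shared by the charged products
    photon_energy: float = 0.0      # MeV, 0 if no photon

    def __post_init__(self) -> None:
        if not 0.0 <= self.branching_fraction <= 1.0:
            raise InvalidArgumentError("branching fraction must lie in [0, 1]")
        if self.kinetic_release <= 0:
            raise InvalidArgumentError("kinetic_release must be positive")
        if self.photon_energy < 0:
            raise InvalidArgumentError("photon_energy must be >= 0")


@dataclass(frozen=True)
class CrossSection:
    value_barn: float
    reference_energy: str

    def __post_init__(self) -> None:
        if self.value_barn < 0:
            raise InvalidArgumentError("cross section must be >= 0")


@dataclass(frozen=True)
class Species:
    name: str
    charge: int
    mass_mev: float


PROTON = Species("proton", 1, PROTON_MASS_MEV)
ALPHA = Species("alpha", 2, ALPHA_MASS_MEV)


@dataclass(frozen=True)
class StoppingModel:
    """Material description for the Bethe collision stopping power.

    ``composition`` is a tuple of ``(element symbol, mass fraction)`` pairs;
    fractions must sum to 1 within 1e-9.
    """

    name: str
    composition: tuple[tuple[str, float], ...]
    density: float                  # g/cm^3
    mean_excitation_ev: float

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"mass fractions must sum to 1 (got {total!r})")
        if self.density <= 0:
            raise InvalidArgumentError("density must be positive")
        for sym, _ in self.composition:
            if sym not in _ELEMENTS:
                raise InvalidArgumentError(f"unknown element {sym!r}")

    @property
    def z_over_a(self) -> float:
        """Electrons per gram divided by N_A: sum_i w_i Z_i / A_i."""
        return sum(f * _ELEMENTS[s][0] / _ELEMENTS[s][1]
                   for s, f in self.composition)

    @classmethod
    def from_fractions(cls, name, fractions, density, mean_excitation_ev):
        return cls(name, tuple(sorted(fractions.items())), density,
                   mean_excitation_ev)


WATER = StoppingModel.from_fractions(
    "water", {"H": 0.111894, "O": 0.888106}, 1.0, 75.0)
AIR = StoppingModel.from_fractions(
    "air", {"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827},
    1.205e-3, 85.7)
# Mylar = PET, (C10H8O4)n
MYLAR = StoppingModel.from_fractions(
    "mylar", {"C": 0.625016, "H": 0.041960, "O": 0.333024}, 1.40, 78.7)
BORON = StoppingModel.from_fractions("boron", {"B": 1.0}, 2.37, 76.0)

MATERIALS = {m.name: m for m in (WATER, AIR, MYLAR, BORON)}


# --- reaction inventory ----------------------------------------------------

B10 = Nuclide("B", 10, 5, F_B10)
B11 = Nuclide("B", 11, 5, F_B11)
HE4 = Nuclide("He", 4, 2)
LI7 = Nuclide("Li", 7, 3)
NEUTRON = Nuclide("n", 1, 0)
PROTON_NUCLIDE = Nuclide("H", 1, 1)

#: 94% branch: the 7Li is left excited and de-excites by a 478 keV photon.
BNCT_EXCITED_CHANNEL = ReactionChannel(
    reactants=(NEUTRON, B10),
    products=((HE4, "alpha"), (LI7, "recoil")),
    branching_fraction=0.94,
    kinetic_release=2.31,
    photon_energy=0.48,
)

#: 6% branch straight to the 7Li ground state; all energy is kinetic.
BNCT_GROUND_CHANNEL = ReactionChannel(
    reactants=(NEUTRON, B10),
    products=((HE4, "alpha"), (LI7, "recoil")),
    branching_fraction=0.06,
    kinetic_release=2.79,
    photon_energy=0.0,
)

#: p + 11B -> 3 alpha; Q = 8.7 MeV, mean ~3 MeV per alpha. The 3-alpha final
#: state is represented downstream by a single mono-energetic 3 MeV surrogate.
PBFT_CHANNEL = ReactionChannel(
    reactants=(PROTON_NUCLIDE, B11),
    products=((HE4, "alpha"), (HE4, "alpha"), (HE4, "alpha")),
    branching_fraction=1.0,
    kinetic_release=8.7,
)

#: fusion cross section on the ~675 keV resonance
SIGMA_PBFT_RESONANCE = CrossSection(1.0, "0.675 MeV resonance")
#: 2200 m/s thermal capture cross sections
SIGMA_B10_THERMAL = CrossSection(3837.0, "thermal (2200 m/s)")
SIGMA_N14_THERMAL = CrossSection(1.83, "thermal (2200 m/s)")


# --- kinematics ------------------------------------------------------------

def solve_two_body(kinetic_release: float, mass_a: float,
                   mass_b: float) -> tuple[float, float]:
    """Split a kinetic release between two products of a capture at rest.

    Non-relativistic momentum balance gives ``E_a = Q · m_b / (m_a + m_b)``,
    so the lighter fragment carries the larger share.

    Parameters
    ----------
    kinetic_release : total kinetic energy Q shared by the two products (MeV).
    mass_a, mass_b : product masses (amu; integer mass numbers suffice).

    Returns
    -------
    ``(E_a, E_b)`` in MeV, summing exactly to ``kinetic_release``.
    """
    if kinetic_release <= 0:
        raise InvalidArgumentError("kinetic_release must be positive")
    if mass_a <= 0 or mass_b <= 0:
        raise InvalidArgumentError("masses must be positive")
    e_a = kinetic_release * mass_b / (mass_a + mass_b)
    return e_a, kinetic_release - e_a


def channel_photon_energy(ground: ReactionChannel,
                          excited: ReactionChannel) -> float:
    """Photon energy of the excited branch as the inter-channel difference.

    The two channels must share reactants and charged products; the
    difference of their kinetic releases is the de-excitation photon energy.
    """
    if ground.reactants != excited.reactants:
        raise InvalidArgumentError("channels do not share reactants")
    if ground.products != excited.products:
        raise InvalidArgumentError("channels do not share charged products")
    e_gamma = ground.kinetic_release - excited.kinetic_release
    if excited.photon_energy > 0 and abs(e_gamma - excited.photon_energy) > 1e-6:
        raise InvalidArgumentError(
            "release difference inconsistent with the declared photon energy")
    return e_gamma


def alpha_yield(sigma_r_barn: float, areal_density_atoms_per_barn: float) -> float:
    """Fusion reactions per incident proton: ``Y = σ_R · n_B``.

    ``n_B`` is the areal density of ¹¹B along the proton path in atoms/barn.
    The thin-target product is only meaningful as a probability well below 1;
    a warning is raised above 0.1.
    """
    if sigma_r_barn < 0 or areal_density_atoms_per_barn < 0:
        raise InvalidArgumentError("inputs must be non-negative")
    y = sigma_r_barn * areal_density_atoms_per_barn
    if y > 0.1:
        warnings.warn(
            f"per-proton reaction probability {y:.3g} exceeds 0.1; "
            "the thin-target formula is unreliable here", stacklevel=2)
    return y


def sphere_mean_chord(radius_um: float) -> float:
    """Cauchy mean chord of a sphere under a uniform parallel flux: 4r/3."""
    if radius_um <= 0:
        raise InvalidArgumentError("radius must be positive")
    return 4.0 * radius_um / 3.0


def boron_sphere_areal_density(radius_um: float, density: float = 2.37,
                               b11_fraction: float = F_B11,
                               atomic_weight: float = _ELEMENTS["B"][1]) -> float:
    """Mean-chord ¹¹B areal density of a solid boron sphere, in atoms/barn."""
    if radius_um <= 0 or density <= 0:
        raise InvalidArgumentError("radius and density must be positive")
    n_per_cm3 = density * AVOGADRO / atomic_weight * b11_fraction
    chord_cm = sphere_mean_chord(radius_um) * CM_PER_UM
    return n_per_cm3 * chord_cm * BARN_TO_CM2


def dissolved_areal_density(ppm_b: float, path_um: float,
                            b11_fraction: float = F_B11,
                            density: float = 1.0,
                            atomic_weight: float = _ELEMENTS["B"][1]) -> float:
    """¹¹B areal density (atoms/barn) of boron dissolved at ``ppm_b`` µg/g."""
    if ppm_b < 0 or path_um < 0:
        raise InvalidArgumentError("inputs must be non-negative")
    n_per_cm3 = ppm_b * 1e-6 * density * AVOGADRO / atomic_weight * b11_fraction
    return n_per_cm3 * path_um * CM_PER_UM * BARN_TO_CM2


# --- stopping power and range ----------------------------------------------

def _bethe_proton(e_mev: float, model: StoppingModel) -> float:
    # collision stopping power of a proton, MeV cm^2/g, no shell/density corr.
    gamma = 1.0 + e_mev / PROTON_MASS_MEV
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_mev = model.mean_excitation_ev * 1e-6
    arg = 2.0 * ME_C2 * beta2 * gamma * gamma / i_mev
    return K_BETHE * model.z_over_a / beta2 * (math.log(arg) - beta2)


@functools.lru_cache(maxsize=None)
def _junction_params(model: StoppingModel) -> tuple[float, float]:
    # value and log-log slope of the proton Bethe curve at the junction;
    # the continuation below is S_j * (E/E_j)^p, matched in value and slope
    e_j = _E_JUNCTION_MEV
    s_j = _bethe_proton(e_j, model)
    h = 1e-4
    slope = ((math.log(_bethe_proton(e_j * (1 + h), model))
              - math.log(_bethe_proton(e_j * (1 - h), model)))
             / (math.log(1 + h) - math.log(1 - h)))
    return s_j, slope


def _proton_mass_stopping(e_mev, model: StoppingModel):
    """Proton mass stopping power (MeV cm^2/g); accepts scalars or arrays."""
    e = np.asarray(e_mev, dtype=float)
    s_j, p = _junction_params(model)
    out = np.empty_like(e)
    lo = e < _E_JUNCTION_MEV
    out[lo] = s_j * (e[lo] / _E_JUNCTION_MEV) ** p
    if np.any(~lo):
        hi = e[~lo]
        gamma = 1.0 + hi / PROTON_MASS_MEV
        beta2 = 1.0 - 1.0 / (gamma * gamma)
        i_mev = model.mean_excitation_ev * 1e-6
        arg = 2.0 * ME_C2 * beta2 * gamma * gamma / i_mev
        out[~lo] = (K_BETHE * model.z_over_a / beta2
                    * (np.log(arg) - beta2))
    return out if out.ndim else float(out)


def _alpha_effective_charge(e_mev):
    # Barkas-style velocity-dependent effective charge for helium ions
    e = np.asarray(e_mev, dtype=float)
    gamma = 1.0 + e / ALPHA_MASS_MEV
    beta = np.sqrt(1.0 - 1.0 / (gamma * gamma))
    z = 2.0
    zeff = z * (1.0 - np.exp(-125.0 * beta / z ** (2.0 / 3.0)))
    return zeff if zeff.ndim else float(zeff)


def _mass_stopping(e_mev, species: Species, model: StoppingModel):
    """Mass stopping power for any supported species, no range validation."""
    if species.name == "proton":
        return _proton_mass_stopping(e_mev, model)
    if species.name == "alpha":
        e = np.asarray(e_mev, dtype=float)
        e_p = e * (PROTON_MASS_MEV / ALPHA_MASS_MEV)   # equal velocity
        out = _alpha_effective_charge(e) ** 2 * _proton_mass_stopping(e_p, model)
        return out if np.ndim(out) else float(out)
    raise InvalidArgumentError(f"unsupported species {species.name!r}")


def stopping_power(e_mev: float, species: Species,
                   model: StoppingModel) -> float:
    """Mass collision stopping power in MeV·cm²/g.

    Bethe formula above the validity junction (0.5 MeV proton-equivalent),
    power-law continuation matched in value and log-log slope below; α
    particles use the proton curve at equal velocity scaled by a Barkas
    effective charge squared. Supported energies: 1 keV – 20 MeV.
    """
    _check_energy(e_mev)
    return float(_mass_stopping(e_mev, species, model))


def let_kev_per_um(e_mev: float, species: Species,
                   model: StoppingModel) -> float:
    """Linear energy transfer S·ρ in keV/µm."""
    return stopping_power(e_mev, species, model) * model.density * 1e3 * 1e-4


def _check_energy(e_mev: float) -> None:
    if not (_E_MIN_MEV <= e_mev <= _E_MAX_MEV):
        raise EnergyRangeError(
            f"energy {e_mev} MeV outside supported range "
            f"[{_E_MIN_MEV}, {_E_MAX_MEV}] MeV")


def csda_range(e_mev: float, species: Species, model: StoppingModel,
               in_um: bool = False) -> float:
    """CSDA range ∫₀ᴱ dE'/S(E') in g/cm² (or µm of the material).

    Evaluated by adaptive quadrature at relative tolerance 1e-6; the
    integrand 1/S vanishes at E → 0, so the lower limit is regular.
    """
    _check_energy(e_mev)
    junction = _E_JUNCTION_MEV
    if species.name == "alpha":
        junction *= ALPHA_MASS_MEV / PROTON_MASS_MEV
    pts = [p for p in (junction,) if 0 < p < e_mev]
    r, _ = quad(lambda e: 1.0 / _mass_stopping(e, species, model),
                0.0, e_mev, points=pts or None, epsrel=1e-6, limit=200)
    if in_um:
        return r / model.density / CM_PER_UM
    return r


class RangeTable:
    """Tabulated range–energy relation for fast transport stepping.

    Log–log cumulative-trapezoid table of ``range(E)`` on a dense grid;
    provides vectorized ``range_of`` and its inverse ``energy_at``.
    """

    def __init__(self, species: Species, model: StoppingModel,
                 n_points: int = 4000):
        self.species = species
        self.model = model
        e = np.geomspace(_E_MIN_MEV / 4.0, _E_MAX_MEV, n_points)
        inv_s = 1.0 / _mass_stopping(e, species, model)
        r = np.concatenate([[0.0], np.cumsum(
            0.5 * (inv_s[1:] + inv_s[:-1]) * np.diff(e))])
        r += csda_range_unchecked(e[0], species, model)
        self._log_e = np.log(e)
        self._log_r = np.log(r)

    def range_of(self, e_mev):
        """Range in g/cm² for energies within the table."""
        return np.exp(np.interp(np.log(np.asarray(e_mev, dtype=float)),
                                self._log_e, self._log_r))

    def energy_at(self, r_gcm2):
        """Inverse relation: energy whose range equals ``r_gcm2``."""
        r = np.asarray(r_gcm2, dtype=float)
        out = np.exp(np.interp(np.log(np.maximum(r, 1e-300)),
                               self._log_r, self._log_e))
        return np.where(r <= np.exp(self._log_r[0]),
                        np.exp(self._log_e[0]), out)


def csda_range_unchecked(e_mev, species, model):
    # quadrature range without the public energy-window validation
    junction = _E_JUNCTION_MEV
    if species.name == "alpha":
        junction *= ALPHA_MASS_MEV / PROTON_MASS_MEV
    pts = [p for p in (junction,) if 0 < p < e_mev]
    r, _ = quad(lambda e: 1.0 / _mass_stopping(e, species, model),
                0.0, e_mev, points=pts or None, epsrel=1e-6, limit=200)
    return r


@functools.lru_cache(maxsize=None)
def get_range_table(species_name: str, model: StoppingModel) -> RangeTable:
    species = {"proton": PROTON, "alpha": ALPHA}[species_name]
    return RangeTable(species, model)


def bohr_straggling_sigma(species: Species, model: StoppingModel,
                          path_gcm2: float) -> float:
    """Bohr energy-straggling standard deviation (MeV) over a path.

    σ² = 0.1569 · z² · (Z/A) · ξ with ξ in g/cm² (non-relativistic Bohr
    variance; adequate for sub-MeV spectral broadening in thin degraders).
    """
    if path_gcm2 < 0:
        raise InvalidArgumentError("path must be non-negative")
    var = 0.1569 * species.charge ** 2 * model.z_over_a * path_gcm2
    return math.sqrt(var)
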