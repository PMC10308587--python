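"""Frequency-dependent material response factors.

The whole frequency dependence of the fluctuating-charge models lives in two
scalar factors:

* ``z(omega) = n0 * tau / (m* (1 - i omega tau))`` — the Drude conduction
  factor (the AC conductivity of the material's free-electron gas, in atomic
  units).  At ``omega = 0`` it reduces to the real static conductivity and its
  magnitude decays as ``1/omega`` for ``omega tau >> 1``.
* ``z'(omega) = 1 / alpha_IB(omega)`` — the inverse interband polarizability
  entering the diagonal of the dipole block of the charge+dipole model.

plus the pairwise Fermi damping ``f(r_ij)`` that switches interatomic
conduction off across sub-nanometer gaps (quantum-tunneling mimic).

Default parameterizations
-------------------------
Parameter values are derived from bulk physics rather than fitted per
structure:

* the per-bond effective conduction areas are chosen so that the atomistic
  nearest-neighbor network reproduces the macroscopic Drude conductivity of
  the material — ``A = sqrt(2)/4 d_nn^2`` for an fcc lattice and
  ``A = s * sqrt(3) d_cc^2`` for the graphene honeycomb sheet;
* graphene uses the Dirac-cone effective mass ``m* = E_F / v_F^2`` and the 3D
  density ``n0 = n2D / d_cc`` so that the sheet carries the intraband Drude
  weight ``E_F / pi`` per unit area; the dimensionless scale ``s`` calibrates
  the conduction channel to the large-disk (r = 160 A) dipolar resonance of
  0.24 eV at ``E_F = 0.4`` eV;
* Gaussian source widths make each atom's electrostatic self-energy equal
  that of its charge spread over a classical volume: a conducting sphere of
  radius ``d_nn/2`` for metals, the 2D Wigner-Seitz cell for graphene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import GeometryError, ParameterError, RangeError
from .units import (
    BOHR_PER_ANGSTROM,
    EV_PER_HARTREE,
    HARTREE_PER_EV,
)

#: graphene Fermi velocity, atomic units (~1e6 m/s)
GRAPHENE_FERMI_VELOCITY = 0.457

#: conduction-area scale for graphene, calibrated to the 160-A-disk resonance
GRAPHENE_AREA_SCALE = 0.7514


@dataclass
class InterbandTable:
    """Tabulated complex interband polarizability alpha_IB(omega).

    ``omega_ev`` must be strictly increasing; interpolation is linear in the
    real and imaginary parts separately and never extrapolates.
    """

    omega_ev: np.ndarray
    alpha_au: np.ndarray  # complex, atomic units

    def __post_init__(self):
        self.omega_ev = np.asarray(self.omega_ev, dtype=float)
        self.alpha_au = np.asarray(self.alpha_au, dtype=complex)
        if self.omega_ev.ndim != 1 or len(self.omega_ev) < 2:
            raise ParameterError("interband table needs >= 2 grid points")
        if np.any(np.diff(self.omega_ev) <= 0):
            raise ParameterError("interband grid must be strictly increasing")
        if np.any(self.alpha_au.imag < -1e-12):
            raise ParameterError("interband table violates passivity (Im alpha < 0)")

    def __call__(self, omega_ev):
        o = float(omega_ev)
        lo, hi = self.omega_ev[0], self.omega_ev[-1]
        if o < lo or o > hi:
            raise RangeError(
                f"omega = {o} eV outside interband table range [{lo}, {hi}] eV"
            )
        re = np.interp(o, self.omega_ev, self.alpha_au.real)
        im = np.interp(o, self.omega_ev, self.alpha_au.imag)
        return complex(re, im)

    @classmethod
    def drude_lorentz(cls, alpha0_au, omega0_ev, gamma_ev, omega_min_ev=0.05,
                      omega_max_ev=10.0, n=400):
        """Analytic single-oscillator table:
        ``alpha(w) = alpha0 * w0^2 / (w0^2 - w^2 - i gamma w)``."""
        grid = np.linspace(omega_min_ev, omega_max_ev, n)
        alpha = alpha0_au * omega0_ev**2 / (
            omega0_ev**2 - grid**2 - 1j * gamma_ev * grid
        )
        return cls(grid, alpha)

    @staticmethod
    def analytic_drude_lorentz_value(alpha0_au, omega0_ev, gamma_ev, omega_ev):
        return alpha0_au * omega0_ev**2 / (
            omega0_ev**2 - omega_ev**2 - 1j * gamma_ev * omega_ev
        )


@dataclass
class MaterialModel:
    """Material parameters of the fluctuating-charge(+dipole) models.

    Lengths are in angstrom at this interface; densities and times in atomic
    units, consistent with the internal unit system.
    """

    name: str
    n0: float                    # electron density, a.u. (bohr^-3)
    tau: float                   # scattering time, a.u.
    effective_mass: float = 1.0
    gaussian_width_q: float = 1.0   # angstrom
    gaussian_width_mu: float = 1.0  # angstrom
    damping_r0: float = 5.0         # angstrom, tunneling onset
    damping_steepness: float = 7.0  # 1/angstrom
    effective_area: float = 1.0     # angstrom^2, per conduction channel
    interband: InterbandTable | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise ParameterError("scattering time tau must be positive")
        if self.n0 < 0:
            raise ParameterError("electron density n0 must be non-negative")
        if self.gaussian_width_q <= 0 or self.gaussian_width_mu <= 0:
            raise ParameterError("gaussian widths must be positive")
        if self.damping_steepness <= 0:
            raise ParameterError("damping steepness must be positive")

    def effective_area_rule(self, i, j, structure=None):
        """Effective area (angstrom^2) of the conduction channel (i, j);
        default: a single per-material constant."""
        return self.effective_area


def drude_response_factor(omega_ev, material):
    """Drude factor z(omega) = n0 tau / (m* (1 - i omega tau)), a.u."""
    if material.tau <= 0:
        raise ParameterError("scattering time tau must be positive")
    if omega_ev < 0:
        raise ParameterError("omega must be >= 0")
    w = omega_ev * HARTREE_PER_EV
    return material.n0 * material.tau / (
        material.effective_mass * (1.0 - 1j * w * material.tau)
    )


def interband_response_factor(omega_ev, material):
    """Interband factor z'(omega) = 1 / alpha_IB(omega), a.u."""
    if material.interband is None:
        raise ParameterError(f"material {material.name!r} has no interband table")
    return 1.0 / material.interband(omega_ev)


def tunneling_damping(r_ij, pair=None, material=None, r0=None, steepness=None):
    """Fermi damping f(r) = 1 / (1 + exp(steepness * (r - r0))) in [0, 1].

    Distances in angstrom.  ``pair`` is accepted for rule-based overrides but
    the default damping is pairwise-uniform per material.
    """
    if r0 is None:
        r0 = material.damping_r0
    if steepness is None:
        steepness = material.damping_steepness
    x = steepness * (np.asarray(r_ij, dtype=float) - r0)
    out = np.empty_like(x, dtype=float)
    pos = x > 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class GrapheneParams:
    """Graphene doping state derived from the Fermi energy."""

    fermi_energy: float       # eV
    fermi_velocity: float     # a.u.
    surface: float            # angstrom^2
    n2d: float                # electrons per angstrom^2
    alpha_doping: float       # doping electrons per carbon atom
    n0: float = field(default=0.0)  # 3D-equivalent density, a.u.


def _cell_area_ang2(cc_bond):
    return (3 * np.sqrt(3) / 4) * cc_bond**2


def graphene_electron_density(fermi_energy_ev, fermi_velocity=GRAPHENE_FERMI_VELOCITY,
                              structure=None, cc_bond=None):
    """Populate the graphene doping state from the Fermi energy.

    The massless Dirac dispersion gives ``n2D = E_F^2 / (pi vF^2)`` (atomic
    units, spin and valley degeneracy included); ``alpha_doping`` is the
    doping charge per carbon atom and ``n0`` the 3D-equivalent density
    obtained by spreading the sheet density over one bond length.
    """
    if fermi_energy_ev < 0:
        raise ParameterError("Fermi energy must be >= 0")
    ef = fermi_energy_ev * HARTREE_PER_EV
    n2d_au = ef**2 / (np.pi * fermi_velocity**2)  # bohr^-2
    n2d_ang2 = n2d_au * BOHR_PER_ANGSTROM**2
    if structure is not None:
        if structure.n_atoms > 3:
            centered = structure.positions - structure.positions.mean(axis=0)
            thickness = np.linalg.svd(centered, compute_uv=False)[-1]
            if thickness > 1e-6:
                raise GeometryError("graphene density requires a planar structure")
        if cc_bond is None:
            cc_bond = structure.first_neighbor_distance()
        surface = structure.n_atoms * _cell_area_ang2(cc_bond)
        n_atoms = structure.n_atoms
    else:
        if cc_bond is None:
            cc_bond = 1.42
        surface = _cell_area_ang2(cc_bond)
        n_atoms = 1
    alpha = n2d_ang2 * surface / n_atoms
    d_bohr = cc_bond * BOHR_PER_ANGSTROM
    n0 = n2d_au / d_bohr
    return GrapheneParams(
        fermi_energy=fermi_energy_ev,
        fermi_velocity=fermi_velocity,
        surface=surface,
        n2d=n2d_ang2,
        alpha_doping=alpha,
        n0=n0,
    )


# ---------------------------------------------------------------------------
# default material factories

def _metal_widths(d_nn_ang):
    # self-energy of a conducting sphere of radius d_nn/2
    return d_nn_ang / (2 * np.sqrt(np.pi))


def _graphene_width(cc_bond):
    # self-energy of the charge spread uniformly over the 2D Wigner-Seitz cell
    r_ws = np.sqrt(_cell_area_ang2(cc_bond) / np.pi) * BOHR_PER_ANGSTROM
    eta = (8.0 / (3.0 * np.pi)) / r_ws          # a.u.
    sigma_bohr = 1.0 / (eta * np.sqrt(np.pi))
    return sigma_bohr / BOHR_PER_ANGSTROM


def _fcc_metal(name, lattice_constant_ang, tau_au, interband):
    a_bohr = lattice_constant_ang * BOHR_PER_ANGSTROM
    d_nn = lattice_constant_ang / np.sqrt(2.0)
    w = _metal_widths(d_nn)
    return MaterialModel(
        name=name,
        n0=4.0 / a_bohr**3,                    # one conduction electron per atom
        tau=tau_au,
        effective_mass=1.0,
        gaussian_width_q=w,
        gaussian_width_mu=w,
        damping_r0=1.8 * d_nn,
        damping_steepness=7.0,
        effective_area=(np.sqrt(2.0) / 4.0) * d_nn**2,
        interband=interband,
    )


def silver(interband=True):
    """Silver: free-electron density of fcc Ag (a = 4.09 A), hbar/tau = 22.8 meV,
    synthetic Drude-Lorentz interband table mimicking the d-band response.
    The oscillator strength is set so that a mid-size cluster's dipolar
    resonance lands at silver's known ~3.4 eV."""
    table = InterbandTable.drude_lorentz(8.0, 4.8, 0.6) if interband else None
    return _fcc_metal("silver", 4.09, 1194.0, table)


def gold(interband=True):
    """Gold: fcc Au (a = 4.08 A), hbar/tau = 71 meV, synthetic Drude-Lorentz
    interband table with the lower d-band onset of Au."""
    table = InterbandTable.drude_lorentz(31.0, 3.5, 0.8) if interband else None
    return _fcc_metal("gold", 4.08, 390.0, table)


def graphene(fermi_energy_ev=0.4, fermi_velocity=GRAPHENE_FERMI_VELOCITY,
             cc_bond=1.42, tau_au=4134.0, structure=None):
    """Graphene sheet material at the given Fermi energy.

    ``tau_au = 4134`` corresponds to a 0.1 ps transport relaxation time.  The
    Dirac effective mass and 3D-equivalent density together carry exactly the
    graphene intraband Drude weight E_F/pi per unit area.
    """
    params = graphene_electron_density(
        fermi_energy_ev, fermi_velocity, structure=structure, cc_bond=cc_bond
    )
    ef = fermi_energy_ev * HARTREE_PER_EV
    m_eff = ef / fermi_velocity**2 if ef > 0 else 1.0
    w = _graphene_width(cc_bond)
    mat = MaterialModel(
        name="graphene",
        n0=params.n0,
        tau=tau_au,
        effective_mass=m_eff,
        gaussian_width_q=w,
        gaussian_width_mu=w,
        damping_r0=1.8 * cc_bond,
        damping_steepness=7.0,
        effective_area=GRAPHENE_AREA_SCALE * np.sqrt(3.0) * cc_bond**2,
        interband=None,
    )
    mat.graphene_params = params
    return mat


DEFAULT_MATERIALS = {"ag": silver, "au": gold, "silver": silver, "gold": gold,
                     "graphene": graphene}


def get_material(material_id, **kwargs):
    try:
        factory = DEFAULT_MATERIALS[material_id.lower()]
    except KeyError:
        raise ParameterError(f"unknown material {material_id!r}") from None
    return factory(**kwargs)


# ---------------------------------------------------------------------------
# material file I/O (YAML key-value with units in the key names)

def save_material(material, path):
    doc = {
        "name": material.name,
        "n0_au": float(material.n0),
        "tau_au": float(material.tau),
        "effective_mass": float(material.effective_mass),
        "gaussian_width_q_ang": float(material.gaussian_width_q),
        "gaussian_width_mu_ang": float(material.gaussian_width_mu),
        "damping_r0_ang": float(material.damping_r0),
        "damping_steepness_per_ang": float(material.damping_steepness),
        "effective_area_ang2": float(material.effective_area),
    }
    if material.interband is not None:
        doc["interband"] = {
            "omega_ev": [float(x) for x in material.interband.omega_ev],
            "alpha_re_au": [float(x) for x in material.interband.alpha_au.real],
            "alpha_im_au": [float(x) for x in material.interband.alpha_au.imag],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def load_material(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    table = None
    if "interband" in doc:
        ib = doc["interband"]
        table = InterbandTable(
            np.asarray(ib["omega_ev"], float),
            np.asarray(ib["alpha_re_au"], float)
            + 1j * np.asarray(ib["alpha_im_au"], float),
        )
    return MaterialModel(
        name=doc["name"],
        n0=doc["n0_au"],
        tau=doc["tau_au"],
        effective_mass=doc.get("effective_mass", 1.0),
        gaussian_width_q=doc["gaussian_width_q_ang"],
        gaussian_width_mu=doc["gaussian_width_mu_ang"],
        damping_r0=doc["damping_r0_ang"],
        damping_steepness=doc["damping_steepness_per_ang"],
        effective_area=doc["effective_area_ang2"],
        interband=table,
    )
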