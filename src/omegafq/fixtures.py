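"""Deterministic synthetic fixtures: toy geometries and Raman-tensor sets.

No reference molecular tensors are shipped; the generator below produces a
*synthetic* stand-in for a quantum-chemistry Raman input.  The underlying
model per mode ``k`` is a smooth polarizability surface

    alpha_k(Q, omega) = lor(omega) * (A0 + A1_k Q + A2_k Q^2 + A3_k Q^3)

with a single electronic Lorentzian ``lor(omega) = w_e^2 / (w_e^2 - w^2 -
i Gamma w)`` (damping Gamma defaults to 0.10 eV, mimicking the finite
lifetime of the molecular excited state), symmetric random mode matrices and
displaced tensors evaluated at ``Q = +/- h``.  Central differences of the
generated tensors therefore converge to the planted derivative with the
usual h^2 error, which the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .geometry import Nanostructure, build_fcc_cluster, build_graphene_disk
from .sers import DEFAULT_STEP_ANG, MoleculeRamanModel, save_raman_tensors
from .units import BOHR_PER_ANGSTROM

DEFAULT_GAMMA_EV = 0.10  # electronic damping of the synthetic tensors


@dataclass
class SyntheticRamanSet:
    """Specification of a synthetic Raman-tensor set."""

    n_modes: int = 3
    mode_freqs_cm: tuple | None = None     # default: spread over 600-1600 cm^-1
    tensor_scale: float = 10.0             # a.u., equilibrium polarizability scale
    derivative_scale: float = 2.0          # a.u./bohr, dalpha/dQ scale
    anisotropy: float = 0.5                # fraction of anisotropic admixture
    pole_ev: float = 5.0                   # electronic resonance of lor(omega)
    gamma_ev: float = DEFAULT_GAMMA_EV
    cubic_scale: float = 0.2               # makes the finite-difference error h^2
    step_ang: float = DEFAULT_STEP_ANG
    site: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.n_modes < 1:
            raise InputError("at least one mode required")
        if self.mode_freqs_cm is None:
            self.mode_freqs_cm = tuple(
                np.linspace(600.0, 1600.0, self.n_modes)
            )
        if len(self.mode_freqs_cm) != self.n_modes:
            raise InputError("mode_freqs_cm length must equal n_modes")


def _lorentz(omega_ev, pole_ev, gamma_ev):
    return pole_ev**2 / (pole_ev**2 - omega_ev**2 - 1j * gamma_ev * omega_ev)


def _random_symmetric(rng, scale, anisotropy):
    iso = scale * (1.0 + 0.3 * rng.standard_normal())
    A = np.eye(3) * iso
    S = rng.standard_normal((3, 3))
    A = A + anisotropy * scale * 0.5 * (S + S.T)
    return A


def generate_synthetic_tensors(spec, seed, omega_ev=1.0, path=None):
    """Generate a deterministic synthetic :class:`MoleculeRamanModel`.

    Same ``spec`` and ``seed`` always produce bitwise-identical tensors (and
    files, when ``path`` is given).
    """
    rng = np.random.default_rng(seed)
    lor = _lorentz(omega_ev, spec.pole_ev, spec.gamma_ev)
    A0 = _random_symmetric(rng, spec.tensor_scale, spec.anisotropy)
    h = spec.step_ang * BOHR_PER_ANGSTROM
    displaced = []
    planted = []
    for _ in range(spec.n_modes):
        A1 = _random_symmetric(rng, spec.derivative_scale, spec.anisotropy)
        A2 = _random_symmetric(rng, spec.derivative_scale * 0.3, spec.anisotropy)
        A3 = _random_symmetric(rng, spec.derivative_scale * spec.cubic_scale,
                               spec.anisotropy)
        ap = lor * (A0 + A1 * h + A2 * h**2 + A3 * h**3)
        am = lor * (A0 - A1 * h + A2 * h**2 - A3 * h**3)
        displaced.append((ap.astype(complex), am.astype(complex)))
        planted.append(lor * A1)
    molecule = MoleculeRamanModel(
        site=np.asarray(spec.site, float),
        mode_freqs_cm=np.asarray(spec.mode_freqs_cm, float),
        alpha_eq=(lor * A0).astype(complex),
        displaced=displaced,
        step_ang=spec.step_ang,
    )
    molecule.planted_derivatives = planted   # ground truth for tests
    if path is not None:
        save_raman_tensors(molecule, path,
                           comment=f"synthetic tensors, seed={seed}, "
                                   f"omega={omega_ev} eV")
    return molecule


# ---------------------------------------------------------------------------
# toy geometries

def dimer(spacing_ang=2.89, element="Ag"):
    """Homonuclear dimer along z, centered at the origin."""
    pos = np.array([[0.0, 0.0, -spacing_ang / 2], [0.0, 0.0, spacing_ang / 2]])
    return Nanostructure(pos, [element] * 2, material_id=element.lower(),
                         neighbor_cutoff=1.2 * spacing_ang)


def square4(spacing_ang=2.89, element="Ag"):
    """Four atoms on a square in the xy plane."""
    s = spacing_ang / 2
    pos = np.array([[-s, -s, 0.0], [s, -s, 0.0], [s, s, 0.0], [-s, s, 0.0]])
    return Nanostructure(pos, [element] * 4, material_id=element.lower(),
                         neighbor_cutoff=1.2 * spacing_ang)


def single_atom(element="Ag"):
    return Nanostructure(np.zeros((1, 3)), [element], material_id=element.lower())


def icosahedron13(element="Ag"):
    return build_fcc_cluster("icosahedron", 1, element=element)


def tip_cluster(element="Ag"):
    """55-atom icosahedron: the fixture tip geometry (vertex along +y)."""
    return build_fcc_cluster("icosahedron", 2, element=element)


def small_graphene_disk(radius_ang=8.0):
    return build_graphene_disk(radius_ang)
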