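"""Assembly and solution of the fluctuating-charge response models.

Model
-----
Each atom ``i`` carries a complex oscillating charge ``q_i`` (and, in the
charge+dipole variant, a complex dipole ``mu_i``).  Charge flows between
conduction neighbors following Drude dynamics; with an ``exp(-i omega t)``
time dependence the charge equation of motion reads

    i omega q  +  z(omega) K (T^qq q + T^qmu mu + V_ext)  =  0

where ``K`` is the (symmetric, zero-row-sum) conduction network operator with
per-bond weights ``f(r_ij) A_ij / r_ij``, ``T^qq`` the Gaussian-screened
charge-charge interaction and ``V_ext_i = -E_ext . r_i`` the quasistatic
external potential.  The zero column sums of ``K`` conserve total charge
structurally.  Dipoles respond through the interband polarizability,

    z'(omega) mu  -  T^muq q  -  T^mumu mu  =  E_ext ,

with ``z' = 1/alpha_IB``.  The geometric operators depend on the structure
only; all frequency dependence is confined to the scalar factors ``z``, ``z'``
and the ``i omega`` diagonal shift, so assemblies are cached and reused across
a frequency scan.

All matrices are built from Gaussian-smeared sources, which keeps every
kernel (and the near field at any point, including atom sites) finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, gmres
from scipy.special import erf

from .errors import GeometryError, RangeError, SolverError
from .materials import (
    drude_response_factor,
    interband_response_factor,
    tunneling_damping,
)
from .units import BOHR_PER_ANGSTROM, HARTREE_PER_EV, SPEED_OF_LIGHT_AU

RESIDUAL_TOL = 1e-10
DENSE_UNKNOWN_LIMIT = 6000

_SQRT_PI = np.sqrt(np.pi)
_G = 2.0 / _SQRT_PI


# ---------------------------------------------------------------------------
# Gaussian-screened kernels (atomic units). S is the combined source width:
# the interaction of two Gaussian charges of widths s1, s2 equals the bare
# Coulomb kernel screened with S = sqrt(s1^2 + s2^2).

def _f1(t):
    """erf(t) - (2/sqrt(pi)) t exp(-t^2): radial screening of the field."""
    return erf(t) - _G * t * np.exp(-t * t)


def charge_potential_kernel(r, S):
    """Potential of a unit Gaussian charge at distance r (a.u.)."""
    r = np.asarray(r, float)
    t = r / (np.sqrt(2.0) * S)
    small = r < 1e-12
    out = np.where(small, _G / (np.sqrt(2.0) * S), erf(t) / np.where(small, 1.0, r))
    return out


def charge_field_radial(r, S):
    """|E| / (q) of a Gaussian charge: f1(t) / r^2, finite at r -> 0."""
    r = np.asarray(r, float)
    t = r / (np.sqrt(2.0) * S)
    r2 = np.where(r < 1e-12, 1.0, r * r)
    out = _f1(t) / r2
    return np.where(r < 1e-12, 0.0, out)


def dipole_tensor(dr, S):
    """Screened dipole interaction tensor T_ab = d_a d_b Phi(r) for
    displacement(s) dr (..., 3); the field of dipole mu is T @ mu."""
    dr = np.asarray(dr, float)
    r = np.linalg.norm(dr, axis=-1)
    safe = np.where(r < 1e-12, 1.0, r)
    t = r / (np.sqrt(2.0) * S)
    u = np.exp(-t * t)
    f1 = erf(t) - _G * t * u
    phi1_over_r = -f1 / safe**3                       # Phi' / r
    phi2 = (2.0 / safe**3) * (erf(t) - _G * t * u * (1.0 + t * t))  # Phi''
    rhat = dr / safe[..., None]
    eye = np.eye(3)
    T = (
        phi2[..., None, None] * rhat[..., :, None] * rhat[..., None, :]
        + phi1_over_r[..., None, None]
        * (eye - rhat[..., :, None] * rhat[..., None, :])
    )
    zero = r < 1e-12
    if np.any(zero):
        T = np.where(zero[..., None, None], 0.0, T)
    return T


# ---------------------------------------------------------------------------
# data containers

@dataclass
class ResponseSolution:
    """Solved per-atom response at one frequency (atomic units)."""

    omega_ev: float
    charges: np.ndarray              # (N,) complex
    dipoles: np.ndarray | None       # (N, 3) complex or None
    e_ext: np.ndarray                # (3,) complex
    induced_dipole: np.ndarray       # (3,) complex

    @property
    def model(self):
        return "wfq" if self.dipoles is None else "wfqfmu"


@dataclass
class AbsorptionSpectrum:
    """Quasistatic absorption cross-section sigma(w) = 4 pi w Im alpha / c."""

    omega_ev: np.ndarray
    cross_section: np.ndarray        # a.u.
    polarization: object             # unit 3-vector or "isotropic"


@dataclass
class FieldMap:
    """Total complex electric field sampled at a set of points."""

    points: np.ndarray               # (P, 3) angstrom
    e_total: np.ndarray              # (P, 3) complex, a.u.
    e_ext: np.ndarray                # (3,) complex, a.u.
    grid_shape: tuple | None = None  # set when points form a regular grid
    spacing: float | None = None     # angstrom


# ---------------------------------------------------------------------------
# assembly

class WfqAssembly:
    """Frequency-independent geometric operators of the charge-only model."""

    def __init__(self, structure, material):
        self.structure = structure
        self.material = material
        R = structure.positions * BOHR_PER_ANGSTROM
        self.R = R
        N = structure.n_atoms
        self.N = N
        sq = material.gaussian_width_q * BOHR_PER_ANGSTROM
        self.sigma_q = sq
        if N:
            dr = R[:, None, :] - R[None, :, :]
            dist = np.linalg.norm(dr, axis=-1)
            S = np.sqrt(2.0) * sq
            self.Tqq = charge_potential_kernel(dist, S)
            np.fill_diagonal(self.Tqq, 1.0 / (sq * _SQRT_PI))
        else:
            self.Tqq = np.zeros((0, 0))
        W = np.zeros((N, N))
        for (i, j), r_ang in zip(structure.pairs, structure.pair_distances):
            f = tunneling_damping(r_ang, pair=(i, j), material=material)
            area = material.effective_area_rule(i, j, structure) * BOHR_PER_ANGSTROM**2
            w = f * area / (r_ang * BOHR_PER_ANGSTROM)
            W[i, j] = w
            W[j, i] = w
        self.K = W - np.diag(W.sum(axis=1))
        self.Aq = self.K @ self.Tqq

    def source_potential(self, e_ext, v_extra=None):
        v = -(self.R @ np.asarray(e_ext, complex))
        if v_extra is not None:
            v = v + np.asarray(v_extra, complex)
        return v

    def solve(self, omega_ev, e_ext, v_extra=None, e_extra=None):
        e_ext = np.asarray(e_ext, dtype=complex)
        N = self.N
        if N == 0:
            return ResponseSolution(omega_ev, np.zeros(0, complex), None, e_ext,
                                    np.zeros(3, complex))
        w = omega_ev * HARTREE_PER_EV
        z = drude_response_factor(omega_ev, self.material)
        M = z * self.Aq + 1j * w * np.eye(N)
        b = -z * (self.K @ self.source_potential(e_ext, v_extra))
        q = _linear_solve(M, b)
        _check_residual(M, q, b)
        p = (q[:, None] * self.R).sum(axis=0)
        return ResponseSolution(omega_ev, q, None, e_ext, p)


class WfqFmuAssembly:
    """Geometric operators of the charge+dipole model (block system)."""

    def __init__(self, structure, material):
        if material.interband is None:
            raise RangeError(
                f"material {material.name!r} has no interband table; "
                "the charge+dipole model requires alpha_IB(omega)"
            )
        self.structure = structure
        self.material = material
        self.base = WfqAssembly(structure, material)
        R = self.base.R
        N = structure.n_atoms
        self.N = N
        sq = material.gaussian_width_q * BOHR_PER_ANGSTROM
        sm = material.gaussian_width_mu * BOHR_PER_ANGSTROM
        if N:
            dr = R[:, None, :] - R[None, :, :]
            # charge->dipole / dipole->charge coupling (shared screened kernel)
            S_qm = np.sqrt(sq**2 + sm**2)
            dist = np.linalg.norm(dr, axis=-1)
            safe = np.where(dist < 1e-12, 1.0, dist)
            gd = charge_field_radial(dist, S_qm) / safe   # f1 / r^3
            G3 = dr * gd[:, :, None]             # field at i from charge at j
            self.Tmuq = G3.transpose(0, 2, 1).reshape(3 * N, N)
            # potential at i from a dipole at j flips the displacement sign
            self.Tqmu = -self.Tmuq.T.copy()
            Tdd = dipole_tensor(dr, np.sqrt(2.0) * sm)  # (N, N, 3, 3)
            idx = np.arange(N)
            Tdd[idx, idx] = 0.0
            self.Tmumu = Tdd.transpose(0, 2, 1, 3).reshape(3 * N, 3 * N)
        else:
            self.Tmuq = np.zeros((0, 0))
            self.Tqmu = np.zeros((0, 0))
            self.Tmumu = np.zeros((0, 0))

    def solve(self, omega_ev, e_ext, v_extra=None, e_extra=None):
        e_ext = np.asarray(e_ext, dtype=complex)
        N = self.N
        if N == 0:
            return ResponseSolution(omega_ev, np.zeros(0, complex),
                                    np.zeros((0, 3), complex), e_ext,
                                    np.zeros(3, complex))
        w = omega_ev * HARTREE_PER_EV
        z = drude_response_factor(omega_ev, self.material)
        zp = interband_response_factor(omega_ev, self.material)
        K = self.base.K
        M = np.zeros((4 * N, 4 * N), dtype=complex)
        M[:N, :N] = z * self.base.Aq + 1j * w * np.eye(N)
        M[:N, N:] = z * (K @ self.Tqmu)
        M[N:, :N] = -self.Tmuq
        M[N:, N:] = zp * np.eye(3 * N) - self.Tmumu
        b = np.zeros(4 * N, dtype=complex)
        b[:N] = -z * (K @ self.base.source_potential(e_ext, v_extra))
        b[N:] = np.tile(e_ext, N)
        if e_extra is not None:
            b[N:] += np.asarray(e_extra, complex).reshape(3 * N)
        x = _linear_solve(M, b)
        _check_residual(M, x, b)
        q = x[:N]
        mu = x[N:].reshape(N, 3)
        p = (q[:, None] * self.base.R).sum(axis=0) + mu.sum(axis=0)
        return ResponseSolution(omega_ev, q, mu, e_ext, p)


def _linear_solve(M, b):
    n = len(b)
    if n <= DENSE_UNKNOWN_LIMIT:
        try:
            return np.linalg.solve(M, b)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular response system ({exc})") from exc
    op = LinearOperator((n, n), matvec=lambda v: M @ v, dtype=complex)
    diag = np.diag(M)
    pre = LinearOperator(
        (n, n), matvec=lambda v: v / np.where(np.abs(diag) > 0, diag, 1.0),
        dtype=complex,
    )
    x, info = gmres(op, b, rtol=RESIDUAL_TOL, atol=0.0, M=pre, maxiter=2000)
    if info != 0:
        raise SolverError(f"iterative solve did not converge (info={info})")
    return x


def _check_residual(M, x, b):
    nb = np.linalg.norm(b)
    if nb == 0:
        return
    res = np.linalg.norm(M @ x - b) / nb
    if res > RESIDUAL_TOL:
        raise SolverError(f"relative residual {res:.2e} exceeds {RESIDUAL_TOL}")


# ---------------------------------------------------------------------------
# public operations

_ASSEMBLY_TYPES = {"wfq": WfqAssembly, "wfqfmu": WfqFmuAssembly}


def assemble(structure, material, model="wfq"):
    """Build (and cache on the structure) the geometric assembly for a model."""
    try:
        cls = _ASSEMBLY_TYPES[model]
    except KeyError:
        raise SolverError(f"unknown response model {model!r}") from None
    cache = getattr(structure, "_omegafq_assembly_cache", None)
    if cache is None:
        cache = {}
        structure._omegafq_assembly_cache = cache
    entry = cache.get(model)
    if entry is None or entry[0] is not material:
        entry = (material, cls(structure, material))
        cache[model] = entry
    return entry[1]


def solve_wfq(structure, material, omega_ev, e_ext):
    """Charge-only response at one frequency; external field in a.u."""
    return assemble(structure, material, "wfq").solve(omega_ev, e_ext)


def solve_wfqfmu(structure, material, omega_ev, e_ext):
    """Charge+dipole response at one frequency; external field in a.u."""
    return assemble(structure, material, "wfqfmu").solve(omega_ev, e_ext)


def substrate_polarizability(structure, material, omega_ev, model="wfq"):
    """Complex 3x3 polarizability: columns are induced dipoles per unit field."""
    if structure.n_atoms == 0:
        return np.zeros((3, 3), dtype=complex)
    asm = assemble(structure, material, model)
    alpha = np.zeros((3, 3), dtype=complex)
    for a in range(3):
        e = np.zeros(3, dtype=complex)
        e[a] = 1.0
        alpha[:, a] = asm.solve(omega_ev, e).induced_dipole
    return alpha


def absorption_spectrum(structure, material, omega_grid_ev, polarization="isotropic",
                        model="wfq"):
    """Quasistatic absorption cross-section over a frequency grid."""
    grid = np.asarray(omega_grid_ev, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise RangeError("frequency grid must be 1D and strictly increasing")
    asm = assemble(structure, material, model)
    values = np.empty_like(grid)
    if isinstance(polarization, str):
        if polarization != "isotropic":
            raise RangeError(f"unknown polarization {polarization!r}")
        pol = None
    else:
        pol = np.asarray(polarization, dtype=float)
        pol = pol / np.linalg.norm(pol)
    for k, o in enumerate(grid):
        w = o * HARTREE_PER_EV
        if pol is None:
            tot = 0.0
            for a in range(3):
                e = np.zeros(3, complex)
                e[a] = 1.0
                sol = asm.solve(o, e)
                tot += sol.induced_dipole[a].imag
            im_alpha = tot / 3.0
        else:
            sol = asm.solve(o, pol.astype(complex))
            im_alpha = (pol @ sol.induced_dipole).imag
        values[k] = 4.0 * np.pi * w * im_alpha / SPEED_OF_LIGHT_AU
    return AbsorptionSpectrum(grid, values,
                              polarization if pol is None else pol)


def find_prf(spectrum):
    """Plasmon resonance frequency: interior absorption maximum, refined by a
    three-point parabolic fit (eV)."""
    x = spectrum.omega_ev
    y = spectrum.cross_section
    if len(x) < 3:
        raise RangeError("spectrum needs at least 3 grid nodes")
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        raise RangeError(
            "absorption maximum lies on the grid boundary; widen the frequency scan"
        )
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    return float(x[i] + 0.5 * (x[i + 1] - x[i]) * (y0 - y2) / denom)


def scan_prf(structure, material, omega_min_ev, omega_max_ev, polarization="isotropic",
             model="wfq", coarse_n=40, fine_n=200):
    """Locate the dipolar plasmon resonance with a coarse scan followed by a
    fine scan spanning +/-50% of the coarse peak; returns (prf_ev, spectrum)."""
    coarse = absorption_spectrum(
        structure, material, np.linspace(omega_min_ev, omega_max_ev, coarse_n),
        polarization, model
    )
    peak = find_prf(coarse)
    lo = max(peak * 0.5, omega_min_ev)
    hi = min(peak * 1.5, omega_max_ev)
    fine = absorption_spectrum(
        structure, material, np.linspace(lo, hi, fine_n), polarization, model
    )
    return find_prf(fine), fine


def induced_field(solution, structure, material, points_ang, grid_shape=None,
                  spacing=None):
    """Total field E_ext + induced field of all smeared charges/dipoles at the
    given points (angstrom in, atomic units out)."""
    pts = np.asarray(points_ang, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise GeometryError("induced_field requires at least one point")
    P = pts * BOHR_PER_ANGSTROM
    R = structure.positions * BOHR_PER_ANGSTROM
    sq = material.gaussian_width_q * BOHR_PER_ANGSTROM
    sm = material.gaussian_width_mu * BOHR_PER_ANGSTROM
    e_tot = np.tile(solution.e_ext.astype(complex), (len(P), 1))
    if structure.n_atoms:
        dr = P[:, None, :] - R[None, :, :]
        dist = np.linalg.norm(dr, axis=-1)
        safe = np.where(dist < 1e-12, 1.0, dist)
        gd = charge_field_radial(dist, sq) / safe    # f1 / r^3
        e_tot += np.einsum("pja,j->pa", dr * gd[:, :, None], solution.charges)
        if solution.dipoles is not None:
            T = dipole_tensor(dr, sm)
            e_tot += np.einsum("pjab,jb->pa", T, solution.dipoles)
    return FieldMap(pts, e_tot, solution.e_ext.astype(complex),
                    grid_shape=grid_shape, spacing=spacing)


def induced_potential(solution, structure, material, points_ang):
    """Electrostatic potential of the smeared sources plus the external
    potential at the given points (a.u.); the consistency oracle for
    :func:`induced_field` (E = -grad V)."""
    pts = np.asarray(points_ang, dtype=float).reshape(-1, 3)
    P = pts * BOHR_PER_ANGSTROM
    R = structure.positions * BOHR_PER_ANGSTROM
    sq = material.gaussian_width_q * BOHR_PER_ANGSTROM
    sm = material.gaussian_width_mu * BOHR_PER_ANGSTROM
    v = -(P @ solution.e_ext.astype(complex))
    if structure.n_atoms:
        dr = P[:, None, :] - R[None, :, :]
        dist = np.linalg.norm(dr, axis=-1)
        v = v + charge_potential_kernel(dist, sq) @ solution.charges
        if solution.dipoles is not None:
            safe = np.where(dist < 1e-12, 1.0, dist)
            gd = charge_field_radial(dist, sm) / safe   # f1 / r^3
            v = v + np.einsum("pja,ja->p", dr * gd[:, :, None], solution.dipoles)
    return v
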