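"""Classical SERS observables on top of the substrate response models.

The molecule is a point polarizable object at a site near the substrate; its
complex polarizability tensors (equilibrium and displaced along each normal
mode) are inputs.  Two enhancement channels are retained:

* the *local field*: the substrate, driven by the external field, enhances
  the field at the molecular site (operator ``L``);
* the *reflected field*: the molecule's own induced dipole polarizes the
  substrate, which acts back on the molecule (operator ``M``, iterated to a
  fixed point) and radiates together with it (operator ``G``).

The dressed tensor observed in the far field is

    alpha_bar = (1 + G) (1 - alpha M)^-1 alpha L

which reduces to ``alpha`` for an empty substrate and to ``L^T alpha L`` when
the back-action is negligible (for substrate operators ``G = (L - 1)^T`` by
reciprocity), the classical ``E^2 x E^2`` enhancement picture.

Raman intensities follow Placzek theory for perpendicular-plane-polarized
incident light collected at 90 degrees:

    I_k  =  (omega - omega_k)^4 / (2 omega_k) * (45 a'^2 + 7 g'^2 + 5 d'^2) / 45

with the isotropic (a'), symmetric-anisotropy (g') and antisymmetric-
anisotropy (d') rotational invariants of d(alpha_bar)/dQ_k; the d'^2 term
vanishes when incident and scattered frequencies coincide, which is the
default working approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError, OmegaFQError, SolverError
from .response import assemble, induced_field
from .units import BOHR_PER_ANGSTROM, HARTREE_PER_CM1, HARTREE_PER_EV

logger = logging.getLogger("omegafq.sers")

DEFAULT_STEP_ANG = 0.001       # normal-mode differentiation step, angstrom
DEFAULT_FWHM_CM1 = 4.0         # Lorentzian convolution width
DEFAULT_BOX_PADDING_ANG = 1.0  # molecular box padding for the E^4 average
DEFAULT_BOX_SPACING_ANG = 0.25
VDW_CONTACT_ANG = 1.7          # molecule-substrate overlap guard

FIXPOINT_TOL = 1e-10
FIXPOINT_MAXITER = 500


# ---------------------------------------------------------------------------
# molecular model

@dataclass
class MoleculeRamanModel:
    """Point molecule with mode-resolved polarizability data.

    ``displaced[k] = (alpha_plus, alpha_minus)`` are the complex 3x3 tensors
    at +/- ``step_ang`` along normal coordinate ``Q_k``; frequencies are in
    cm^-1 and the site in angstrom.
    """

    site: np.ndarray
    mode_freqs_cm: np.ndarray
    alpha_eq: np.ndarray
    displaced: list
    step_ang: float = DEFAULT_STEP_ANG
    box: tuple | None = None   # ((lo3,), (hi3,)) angstrom

    def __post_init__(self):
        self.site = np.asarray(self.site, dtype=float).reshape(3)
        self.mode_freqs_cm = np.asarray(self.mode_freqs_cm, dtype=float)
        self.alpha_eq = np.asarray(self.alpha_eq, dtype=complex).reshape(3, 3)
        if np.any(self.mode_freqs_cm <= 0):
            raise InputError("mode frequencies must be positive")
        if len(self.displaced) != len(self.mode_freqs_cm):
            raise InputError("one (plus, minus) tensor pair required per mode")
        for k, pair in enumerate(self.displaced):
            if pair is None or len(pair) != 2 or pair[0] is None or pair[1] is None:
                raise InputError(f"mode {k}: missing displaced tensor pair")
        if self.step_ang <= 0:
            raise InputError("differentiation step must be positive")
        if self.box is None:
            pad = DEFAULT_BOX_PADDING_ANG
            self.box = (self.site - pad, self.site + pad)
        lo, hi = (np.asarray(b, float) for b in self.box)
        if np.any(hi <= lo):
            raise InputError("molecular box must have positive volume")
        self.box = (lo, hi)

    @property
    def n_modes(self):
        return len(self.mode_freqs_cm)


# ---------------------------------------------------------------------------
# substrate coupling operators

@dataclass
class SubstrateCoupling:
    """Linear substrate operators seen by a point molecule at one frequency.

    ``local_field`` (L) maps the external field to the total driving field at
    the site; ``back_action`` (M) maps the molecular dipole to the substrate
    field it induces back at the site; ``emission`` (G) maps the molecular
    dipole to the total substrate dipole it induces (the reflected part of
    the scattered field).
    """

    local_field: np.ndarray
    back_action: np.ndarray
    emission: np.ndarray
    omega_ev: float | None = None

    @classmethod
    def empty(cls, omega_ev=None):
        z = np.zeros((3, 3), dtype=complex)
        return cls(np.eye(3, dtype=complex), z.copy(), z.copy(), omega_ev)

    @classmethod
    def uniform(cls, enhancement, omega_ev=None):
        """Synthetic isotropic coupling: field at the site is ``enhancement``
        times the external field, no back-action; the emission operator is
        fixed by reciprocity, G = (L - 1)^T."""
        ell = complex(enhancement)
        L = ell * np.eye(3, dtype=complex)
        return cls(L, np.zeros((3, 3), complex), (L - np.eye(3)).T.copy(), omega_ev)

    @classmethod
    def from_substrate(cls, structure, material, omega_ev, site_ang, model="wfq"):
        """Compute L, M, G from six substrate solves (three unit external
        fields, three unit point dipoles at the site)."""
        site = np.asarray(site_ang, dtype=float).reshape(3)
        if structure.n_atoms:
            dmin = np.linalg.norm(structure.positions - site, axis=1).min()
            if dmin < VDW_CONTACT_ANG:
                raise GeometryError(
                    f"molecule site {dmin:.2f} A from the nearest substrate atom "
                    f"(inside the {VDW_CONTACT_ANG} A van der Waals contact)"
                )
        else:
            return cls.empty(omega_ev)
        asm = assemble(structure, material, model)
        L = np.zeros((3, 3), dtype=complex)
        M = np.zeros((3, 3), dtype=complex)
        G = np.zeros((3, 3), dtype=complex)
        for a in range(3):
            e = np.zeros(3, dtype=complex)
            e[a] = 1.0
            sol = asm.solve(omega_ev, e)
            fm = induced_field(sol, structure, material, site[None, :])
            L[:, a] = fm.e_total[0]
        R = structure.positions * BOHR_PER_ANGSTROM
        s = site * BOHR_PER_ANGSTROM
        dr = R - s[None, :]
        dist = np.linalg.norm(dr, axis=1)
        from .response import charge_field_radial, dipole_tensor
        sq = material.gaussian_width_q * BOHR_PER_ANGSTROM
        sm = material.gaussian_width_mu * BOHR_PER_ANGSTROM
        gd = charge_field_radial(dist, sq) / np.where(dist < 1e-12, 1.0, dist)
        has_dipoles = model == "wfqfmu"
        Tsub = dipole_tensor(dr, sm) if has_dipoles else None
        for b in range(3):
            p = np.zeros(3, dtype=complex)
            p[b] = 1.0
            # sources the molecular dipole creates on the substrate atoms
            v_mol = (dr @ p) * gd
            e_mol = np.einsum("jab,b->ja", Tsub, p) if has_dipoles else None
            sol = asm.solve(omega_ev, np.zeros(3, complex),
                            v_extra=v_mol, e_extra=e_mol)
            fm = induced_field(sol, structure, material, site[None, :])
            M[:, b] = fm.e_total[0]     # e_ext = 0: purely the substrate field
            G[:, b] = sol.induced_dipole
        return cls(L, M, G, omega_ev)


def dressed_polarizability(alpha_mol, coupling=None, reflected=True,
                           tol=FIXPOINT_TOL, maxiter=FIXPOINT_MAXITER):
    """Self-consistently dressed molecular polarizability tensor.

    ``alpha_mol`` is the bare complex 3x3 tensor; ``coupling`` the
    :class:`SubstrateCoupling` (None or empty -> the bare tensor is returned
    unchanged).  ``reflected=False`` switches off the back-action fixed point
    (operator M) while keeping the local-field and emission channels.
    """
    alpha = np.asarray(alpha_mol, dtype=complex).reshape(3, 3)
    if coupling is None:
        return alpha.copy()
    L, M, G = coupling.local_field, coupling.back_action, coupling.emission
    drive = alpha @ L                     # columns: alpha (L e_a)
    if not reflected or not np.any(M):
        dressed = drive
    else:
        aM = alpha @ M
        p = drive.copy()
        for _ in range(maxiter):
            p_new = drive + aM @ p
            if np.linalg.norm(p_new - p) <= tol * max(np.linalg.norm(p_new), 1e-300):
                p = p_new
                break
            p = p_new
        else:
            raise SolverError(
                "reflected-field fixed point did not converge; the molecule may "
                "be unphysically close to the substrate (consider a direct "
                "block solve)"
            )
        dressed = p
    return dressed + G @ dressed


# ---------------------------------------------------------------------------
# Placzek invariants and intensities

@dataclass
class RamanInvariants:
    """Rotational invariants of a (complex) polarizability-derivative tensor."""

    a_prime: complex     # isotropic part Tr(A)/3 of the incident-frequency tensor
    a_prime2: float      # |a'|^2 (mixed product for two-frequency input)
    g_prime2: float      # symmetric anisotropy
    d_prime2: float      # antisymmetric anisotropy


def raman_invariants(dalpha_dq, incident_omega_ev=None, scattered_omega_ev=None,
                     dalpha_dq_scattered=None):
    """Placzek rotational invariants.

    With a single tensor the usual one-frequency invariants are returned.
    When ``dalpha_dq_scattered`` (the derivative tensor evaluated at the
    scattered frequency) is supplied, the mixed two-frequency invariants are
    formed; the antisymmetric invariant is built from
    ``(A(omega) - A(omega')^T)/2`` and therefore vanishes identically for
    symmetric tensors at equal frequencies.
    """
    A = np.asarray(dalpha_dq, dtype=complex).reshape(3, 3)
    if not np.all(np.isfinite(A)):
        raise InputError("polarizability derivative tensor is not finite")
    B = A if dalpha_dq_scattered is None else (
        np.asarray(dalpha_dq_scattered, dtype=complex).reshape(3, 3)
    )
    trA = np.trace(A)
    trB = np.trace(B)
    a_prime = trA / 3.0
    a2 = float(np.real(trA * np.conj(trB))) / 9.0
    SA = 0.5 * (A + A.T)
    SB = 0.5 * (B + B.T)
    g2 = float(np.real(1.5 * np.sum(SA * np.conj(SB)) - 0.5 * trA * np.conj(trB)))
    D = 0.5 * (A - B.T)
    d2 = float(np.real(1.5 * np.sum(D * np.conj(D))))
    return RamanInvariants(a_prime=a_prime, a_prime2=a2, g_prime2=g2, d_prime2=d2)


def placzek_intensity(invariants, omega_ev, omega_k_cm1):
    """Stokes Raman intensity of one mode (atomic units, 90-degree
    perpendicular-polarized collection)."""
    w = omega_ev * HARTREE_PER_EV
    wk = omega_k_cm1 * HARTREE_PER_CM1
    if w <= wk:
        raise NotImplementedError(
            "anti-Stokes/over-resonant request: incident frequency must exceed "
            "the mode frequency"
        )
    combo = (45.0 * invariants.a_prime2 + 7.0 * invariants.g_prime2
             + 5.0 * invariants.d_prime2) / 45.0
    return float((w - wk) ** 4 / (2.0 * wk) * combo)


def mode_derivatives(molecule, coupling=None, reflected=True):
    """Central-difference derivative of the (dressed) polarizability along
    each normal mode: (alpha_bar(+h) - alpha_bar(-h)) / (2h), a.u. per bohr."""
    h_bohr = molecule.step_ang * BOHR_PER_ANGSTROM
    out = []
    for k in range(molecule.n_modes):
        pair = molecule.displaced[k]
        if pair is None or pair[0] is None or pair[1] is None:
            raise InputError(f"mode {k}: displaced tensors missing")
        ap = dressed_polarizability(pair[0], coupling, reflected=reflected)
        am = dressed_polarizability(pair[1], coupling, reflected=reflected)
        out.append((ap - am) / (2.0 * h_bohr))
    return out


# ---------------------------------------------------------------------------
# field enhancement

def box_grid(lo, hi, spacing=DEFAULT_BOX_SPACING_ANG):
    """Regular grid covering an axis-aligned box (angstrom)."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    axes = [np.linspace(lo[a], hi[a], max(int(round((hi[a] - lo[a]) / spacing)) + 1, 2))
            for a in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    shape = tuple(len(ax) for ax in axes)
    return pts, shape, axes


def upsilon_vol4(fieldmap):
    """Volume average of |E_tot|^4 / |E_ext|^4 over the sampled box.

    Uses trapezoidal weights when the map carries a regular-grid shape and a
    plain mean otherwise.
    """
    e_ext2 = float(np.sum(np.abs(fieldmap.e_ext) ** 2))
    if e_ext2 == 0:
        raise OmegaFQError("upsilon^4 is undefined for a zero external field")
    ratio4 = (np.sum(np.abs(fieldmap.e_total) ** 2, axis=-1) / e_ext2) ** 2
    if fieldmap.grid_shape is None:
        return float(np.mean(ratio4))
    vals = ratio4.reshape(fieldmap.grid_shape)
    w = 1.0
    for axis, n in enumerate(fieldmap.grid_shape):
        wa = np.ones(n)
        wa[0] = wa[-1] = 0.5
        shape = [1, 1, 1]
        shape[axis] = n
        w = w * wa.reshape(shape)
    return float(np.sum(vals * w) / np.sum(w))


def upsilon_at_point(structure, material, omega_ev, point_ang, polarization,
                     model="wfq"):
    """|E_tot/E_ext|^4 at a single point (the site-local E^4 estimator)."""
    asm = assemble(structure, material, model)
    pol = np.asarray(polarization, dtype=complex)
    sol = asm.solve(omega_ev, pol / np.linalg.norm(pol))
    fm = induced_field(sol, structure, material, np.asarray(point_ang)[None, :])
    return upsilon_vol4(FieldMapScalarView(fm))


class FieldMapScalarView:
    """Single-point view reusing the volume-average reduction."""

    def __init__(self, fm):
        self.e_total = fm.e_total
        self.e_ext = fm.e_ext
        self.grid_shape = None


# ---------------------------------------------------------------------------
# enhancement factors and spectra

@dataclass
class SERSResult:
    """Mode-resolved SERS output."""

    mode_freqs_cm: np.ndarray
    intensity_vac: np.ndarray
    intensity_ps: np.ndarray
    ef: np.ndarray
    aef: float
    mef: float
    upsilon4: float | None = None
    omega_ev: float | None = None
    spectrum_grid_cm: np.ndarray | None = None
    spectrum_vac: np.ndarray | None = None
    spectrum_ps: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def enhancement_report(intensity_ps, intensity_vac, mode_freqs_cm=None):
    """EF per mode, spectrally averaged AEF and maximum MEF.

    ``EF_k = I_PS,k / I_vac,k``; ``AEF = sum_k I_PS,k / sum_l I_vac,l`` over
    modes with positive gas-phase intensity (the intensity-weighted average
    of the EF_k); ``MEF = max_k EF_k``.
    """
    i_ps = np.asarray(intensity_ps, dtype=float)
    i_vac = np.asarray(intensity_vac, dtype=float)
    if i_ps.shape != i_vac.shape:
        raise InputError("intensity arrays must share the mode list")
    valid = i_vac > 0
    if not np.all(valid):
        excluded = np.flatnonzero(~valid)
        logger.warning(
            "excluding %d mode(s) with zero gas-phase intensity from AEF: %s",
            len(excluded), excluded.tolist(),
        )
    if not np.any(valid):
        raise InputError("no mode has positive gas-phase intensity")
    ef = np.full_like(i_ps, np.nan)
    ef[valid] = i_ps[valid] / i_vac[valid]
    aef = float(i_ps[valid].sum() / i_vac[valid].sum())
    mef = float(np.nanmax(ef))
    freqs = (np.asarray(mode_freqs_cm, float) if mode_freqs_cm is not None
             else np.arange(len(i_ps), dtype=float))
    return SERSResult(freqs, i_vac, i_ps, ef, aef, mef)


def convolve_spectrum(sticks, fwhm_cm1=DEFAULT_FWHM_CM1, grid_cm=None, pad_cm=50.0,
                      n_points=2000):
    """Lorentzian convolution of a stick spectrum.

    Each stick (position cm^-1, intensity) becomes an area-normalized
    Lorentzian of the given full width at half maximum scaled by the stick
    intensity; the returned spectrum therefore integrates to the summed stick
    intensities.
    """
    if fwhm_cm1 <= 0:
        raise InputError("fwhm must be positive")
    sticks = list(sticks)
    if not sticks:
        logger.warning("convolve_spectrum called with no sticks")
        g = np.asarray(grid_cm, float) if grid_cm is not None else np.zeros(0)
        return g, np.zeros_like(g)
    pos = np.array([s[0] for s in sticks], dtype=float)
    inten = np.array([s[1] for s in sticks], dtype=float)
    if grid_cm is None:
        grid_cm = np.linspace(pos.min() - pad_cm, pos.max() + pad_cm, n_points)
    grid_cm = np.asarray(grid_cm, dtype=float)
    gamma = fwhm_cm1 / 2.0
    lor = (gamma / np.pi) / ((grid_cm[None, :] - pos[:, None]) ** 2 + gamma**2)
    return grid_cm, inten @ lor


def compute_sers(structure, material, molecule, omega_ev, model="wfq",
                 polarization=(0.0, 1.0, 0.0), reflected=True,
                 box_spacing_ang=DEFAULT_BOX_SPACING_ANG, fwhm_cm1=DEFAULT_FWHM_CM1,
                 with_upsilon=True):
    """Full classical SERS pipeline at one excitation frequency.

    Computes gas-phase and substrate-dressed Placzek intensities for every
    mode, enhancement factors, the volume-averaged E^4 estimator over the
    molecular box, and Lorentzian-convolved spectra on the Raman-shift axis.
    """
    inten_vac = []
    derivs_vac = mode_derivatives(molecule, coupling=None)
    for k, dA in enumerate(derivs_vac):
        inv = raman_invariants(dA)
        inten_vac.append(placzek_intensity(inv, omega_ev, molecule.mode_freqs_cm[k]))
    if structure is not None and structure.n_atoms:
        coupling = SubstrateCoupling.from_substrate(
            structure, material, omega_ev, molecule.site, model=model
        )
    else:
        coupling = None
    inten_ps = []
    derivs_ps = mode_derivatives(molecule, coupling=coupling, reflected=reflected)
    for k, dA in enumerate(derivs_ps):
        inv = raman_invariants(dA)
        inten_ps.append(placzek_intensity(inv, omega_ev, molecule.mode_freqs_cm[k]))
    result = enhancement_report(inten_ps, inten_vac, molecule.mode_freqs_cm)
    result.omega_ev = omega_ev
    ups = None
    if with_upsilon and coupling is not None:
        pol = np.asarray(polarization, dtype=complex)
        pol = pol / np.linalg.norm(pol)
        asm = assemble(structure, material, model)
        sol = asm.solve(omega_ev, pol)
        pts, shape, _ = box_grid(*molecule.box, spacing=box_spacing_ang)
        fm = induced_field(sol, structure, material, pts, grid_shape=shape,
                           spacing=box_spacing_ang)
        ups = upsilon_vol4(fm)
    result.upsilon4 = ups
    shift = molecule.mode_freqs_cm
    grid, spec_vac = convolve_spectrum(list(zip(shift, result.intensity_vac)),
                                       fwhm_cm1=fwhm_cm1)
    _, spec_ps = convolve_spectrum(list(zip(shift, result.intensity_ps)),
                                   fwhm_cm1=fwhm_cm1, grid_cm=grid)
    result.spectrum_grid_cm = grid
    result.spectrum_vac = spec_vac
    result.spectrum_ps = spec_ps
    return result


# ---------------------------------------------------------------------------
# Raman tensor file format (plain text, one block per mode)

def _write_tensor(fh, tag, A):
    fh.write(f"  {tag}\n")
    for row in np.asarray(A, complex).reshape(3, 3):
        fh.write("   " + " ".join(f"{v.real: .12e} {v.imag: .12e}" for v in row) + "\n")


def save_raman_tensors(molecule, path, comment=""):
    with open(path, "w") as fh:
        fh.write("# omegafq raman tensor set v1\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"site_ang {molecule.site[0]} {molecule.site[1]} {molecule.site[2]}\n")
        fh.write(f"step_ang {molecule.step_ang}\n")
        fh.write(f"nmodes {molecule.n_modes}\n")
        _write_tensor(fh, "equilibrium", molecule.alpha_eq)
        for k in range(molecule.n_modes):
            fh.write(f"mode {k} freq_cm {molecule.mode_freqs_cm[k]}\n")
            _write_tensor(fh, "plus", molecule.displaced[k][0])
            _write_tensor(fh, "minus", molecule.displaced[k][1])
    return path


def _read_tensor(lines, ln):
    rows = []
    for r in range(3):
        parts = lines[ln + r].split()
        if len(parts) != 6:
            raise InputError(f"tensor row at line {ln + r + 1} malformed")
        vals = [float(p) for p in parts]
        rows.append([complex(vals[0], vals[1]), complex(vals[2], vals[3]),
                     complex(vals[4], vals[5])])
    return np.array(rows), ln + 3


def load_raman_tensors(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    stripped = [l.strip() for l in lines
                if l.strip() and not l.strip().startswith("#")]
    site = step = nmodes = None
    alpha_eq = None
    freqs, displaced = [], []
    pos = 0
    while pos < len(stripped):
        line = stripped[pos]
        tok = line.split()
        if tok[0] == "site_ang":
            site = [float(x) for x in tok[1:4]]
            pos += 1
        elif tok[0] == "step_ang":
            step = float(tok[1])
            pos += 1
        elif tok[0] == "nmodes":
            nmodes = int(tok[1])
            pos += 1
        elif tok[0] == "equilibrium":
            rows = []
            for r in range(1, 4):
                vals = [float(p) for p in stripped[pos + r].split()]
                rows.append([complex(vals[0], vals[1]), complex(vals[2], vals[3]),
                             complex(vals[4], vals[5])])
            alpha_eq = np.array(rows)
            pos += 4
        elif tok[0] == "mode":
            freqs.append(float(tok[3]))
            tensors = {}
            pos += 1
            for _ in range(2):
                tag = stripped[pos]
                rows = []
                for r in range(1, 4):
                    vals = [float(p) for p in stripped[pos + r].split()]
                    rows.append([complex(vals[0], vals[1]),
                                 complex(vals[2], vals[3]),
                                 complex(vals[4], vals[5])])
                tensors[tag] = np.array(rows)
                pos += 4
            if "plus" not in tensors or "minus" not in tensors:
                raise InputError(f"mode {len(freqs) - 1}: needs plus and minus blocks")
            displaced.append((tensors["plus"], tensors["minus"]))
        else:
            raise InputError(f"unrecognized line in tensor file: {line!r}")
    if site is None or step is None or alpha_eq is None:
        raise InputError("tensor file missing site/step/equilibrium header")
    if nmodes is not None and nmodes != len(freqs):
        raise InputError(f"declared {nmodes} modes but found {len(freqs)}")
    return MoleculeRamanModel(site, freqs, alpha_eq, displaced, step_ang=step)
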