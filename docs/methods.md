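# Methods

This note records the physical model, the provenance of every default
parameter, the numerical choices, and what the synthetic fixtures do and do
not demonstrate.

## Substrate response models

Each atom of the nanostructure carries a complex induced charge (and, in the
charge+dipole variant, a complex induced point dipole) oscillating with the
external field. The models are classical and quasistatic: the external
field is uniform over the structure and retardation is neglected, which is
accurate for structures far below the optical wavelength (largest structure
run here: 4 nm).

**Charge dynamics.** Drude conduction between nearest neighbors gives, for
an e^(−iωt) time dependence,

    iω q_i = −z(ω) Σ_j w_ij (φ_j − φ_i),   w_ij = f(r_ij) A_ij / r_ij

with z(ω) = n0 τ / m*(1 − iωτ) the AC Drude conductivity of the material and
φ the total electrochemical potential (smeared Coulomb interaction of all
charges and dipoles plus the external potential). Writing the right side
through the symmetric zero-row-sum network operator K yields the linear
system solved in `response.py`. Because the column sums of K vanish, total
charge is conserved structurally, to solver precision (~1e-14), for any
neutral structure and any field. With this sign convention Im z ≥ 0 and the
response is passive (Im α ≥ 0), which the tests assert.

**Dipoles.** Interband (bound d-electron) screening enters through one
complex polarizability per atom: μ_i = α_IB(ω) E_tot,i, assembled as the
block system with z′(ω) = 1/α_IB(ω) on the dipole diagonal. A single atom
with no conduction partner reproduces α_IB(ω) identically — the isolated-
dipole limit used as an exact test.

**Electrostatic kernels.** All sources are spherical Gaussians, so every
kernel is the erf-screened form of the bare Coulomb/dipole kernel and every
field is finite everywhere, including at atom sites. The charge width is
set by a classical self-energy argument: the atom's self-interaction equals
that of its charge spread over a physical volume — a conducting sphere of
radius d_nn/2 for metals, the 2D Wigner–Seitz cell for graphene (0.61 Å for
C–C 1.42 Å). Dipole widths equal charge widths.

**Solver.** Dense complex LU up to 6000 unknowns (residual checked against
1e-10); beyond that, GMRES with a diagonal preconditioner on the assembled
operator at the same tolerance. The geometric operators depend only on the
structure and are cached, so a frequency scan reassembles nothing — solutions
from the cache are bitwise identical to fresh assemblies.

## Material parameterizations

No fitted per-structure parameters are used; defaults derive from bulk
physics and are fully exposed in the material files.

* **Metals.** One conduction electron per atom: n0 = 4/a³ (Ag a = 4.09 Å,
  Au a = 4.08 Å). Scattering times from Drude fits of the bulk optical
  response: ħ/τ = 22.8 meV (Ag), 71 meV (Au). The per-bond effective area
  A = (√2/4) d_nn² is derived, not fitted: it is the unique value for which
  the nearest-neighbor conduction network of an fcc lattice reproduces the
  macroscopic bulk conductivity (resistor-network homogenization). With it,
  a pure-Drude fcc sphere converges to the classical ω_p/√3 dipole
  resonance from below as 1/R (checked numerically: 4.85 → 4.94 eV for
  1289 → 3055 atoms against 5.18 eV).
* **Interband tables.** Shipping experimental permittivity data is out of
  scope, so α_IB(ω) defaults to a *synthetic* single-oscillator
  Drude–Lorentz table (and any user table can be supplied as delimited
  text). The silver oscillator strength (α0 = 8 a.u., pole 4.8 eV, width
  0.6 eV) is chosen so that a mid-size cluster's dipolar resonance lands at
  silver's known ~3.4 eV once atomistic local-field effects act; gold
  (α0 = 31 a.u., pole 3.5 eV) reproduces the qualitative gold behavior —
  no separate dipolar resonance for small clusters, which only emerges at
  larger radii. These tables are physically representative, not fits to
  measured permittivities; absolute metal numbers should be read
  accordingly.
* **Graphene.** The Dirac dispersion fixes everything from the Fermi
  energy: n_2D = E_F²/(π v_F²), m* = E_F/v_F² (v_F = 0.457 a.u.), and
  n0 = n_2D/d_cc, so the sheet carries exactly the graphene intraband Drude
  weight E_F/π per unit area. τ = 4134 a.u. (0.1 ps) is a typical transport
  relaxation time; the peak position is insensitive to it. The conduction
  area starts from the honeycomb homogenization value √3 d_cc² (which makes
  the atomistic sheet conductivity exactly the Dirac sheet conductivity)
  multiplied by a single dimensionless scale s = 0.7514 calibrated so the
  model reproduces the 0.24 eV dipolar resonance of the large (r = 160 Å)
  disk at E_F = 0.4 eV reported for the reference graphene
  parameterization, whose numeric values are not published. The calibration
  was done by extrapolating the model's disk eigenvalue ζ(R) =
  ω²R/E_F = 2.1621 − 5.235/R[Å] from dense solves at r = 20–56 Å. The
  small-disk (r = 20 Å) resonance is then a prediction: the model gives
  0.642 eV against the reference 0.61 eV (+5%). The residual reflects
  size-dependent physics (nonlocality, edge quantization) that the
  reference parameterization absorbs into its fit and that a local
  classical model cannot supply; we deliberately do not add a second fitted
  parameter to remove it.
* **Tunneling damping.** f(r) = 1/(1 + exp[s(r − r0)]) with r0 = 1.8 d_nn
  and s = 7 Å⁻¹: conduction is fully on at bonded distances and fully off
  beyond ~1 Å of additional gap, the behavior that matters for fragmented
  structures and junctions.

## Geometry conventions

Clusters are closed-shell ideal polyhedra centered at the origin with the
adsorption feature along +y: Mackay icosahedra (radial shell spacing d_nn,
vertex on +y), fcc cuboctahedra (cube ∩ octahedron cut, ⟨110⟩ vertex on
+y), and pentagonal decahedra built from five barycentric-filled strained
fcc tetrahedra sharing the five-fold y axis, apex-truncated for three or
more shells (Ino-style square facets). Graphene disks lie in the xz plane,
centered on a hexagon center (so "the disk center" is unambiguous for
molecule placement), with atoms of fewer than two neighbors pruned
iteratively to a fixed point. Conduction neighbor cutoffs: 1.2× the
first-neighbor distance (metals), 1.1× the C–C bond (graphene).

## SERS layer

The quantum molecule is replaced by a classical point object whose complex
polarizability tensors (equilibrium and displaced ±h along each normal
mode) are inputs; normal-mode frequencies come from the isolated molecule.
Two enhancement channels are kept, matching the two physical contributions
to the scattered field:

1. *Local field*: operator L, the total field at the site per unit external
   field, from three substrate solves.
2. *Reflected field*: the substrate's response to the molecular dipole —
   back-action M on the driving field (resummed by fixed-point iteration to
   1e-10; divergence signals an unphysically close molecule and raises) and
   the emission operator G (substrate dipole induced per molecular dipole),
   which interferes with the molecular dipole in the far field. For a
   reciprocal substrate G = (L − 1)ᵀ, which the tests verify to 1e-8.

The dressed tensor ᾱ = (1 + G)(1 − αM)⁻¹αL reduces to α with no substrate
and to LᵀαL when back-action is negligible — the classical E²×E² picture.
With an isotropic local field L = ℓ·1 and back-action off, every mode's EF
equals |ℓ|⁴, identically the site E⁴ ratio; this closed-form identity is an
exact acceptance test.

**Intensities.** Placzek theory for perpendicular-plane-polarized incident
light collected at 90°: I ∝ (ω − ω_k)⁴/(2ω_k) · (45α′² + 7γ′² + 5δ′²)/45,
with complex-tensor rotational invariants (α′² = |TrA|²/9; γ′² =
(3/2)Σ|S|² − |TrA|²/2 over the symmetric part; δ′² = (3/2)Σ|D|² over the
antisymmetric part). The weights were cross-checked against brute-force
Monte-Carlo orientation averaging of |α_zz|² + |α_xz|². The antisymmetric
term is built, in the two-frequency form, from (A(ω) − A(ω′)ᵀ)/2 and
vanishes identically at equal frequencies for the symmetric tensors of
linear response; the equal-frequency form is the default working
approximation, the general one sits behind the `dalpha_dq_scattered`
argument.

**Enhancement factors.** EF_k = I_PS,k/I_vac,k; AEF = ΣI_PS/ΣI_vac over
modes with positive gas-phase intensity (the intensity-weighted mean EF;
zero-intensity modes are excluded with a logged warning); MEF = max EF.
The E⁴ estimator Υ⁴_vol averages |E_tot|⁴/|E_ext|⁴ over the molecular box
(default: site ± 1 Å, trapezoidal weights on a 0.25 Å grid). Spectra are
sums of area-normalized Lorentzians (default fwhm 4 cm⁻¹) scaled by stick
intensities.

**Numerical defaults.** Differentiation step h = 0.001 Å (central
differences; the h² error is verified by Richardson halving); fixed-point
tolerance 1e-10; molecule–substrate contact guard 1.7 Å; PRF location by a
coarse 40-node scan followed by a 200-node scan spanning ±50% of the coarse
peak and a 3-point parabolic refinement.

## Synthetic fixtures: what they show and what they do not

The tensor generator plants a smooth per-mode polarizability surface
α(Q, ω) = lor(ω)(A0 + A1Q + A2Q² + A3Q³) with symmetric random matrices and
a single electronic Lorentzian (damping 0.10 eV). It is deterministic under
a seed, passive near its pole, and its planted derivatives make the
finite-difference pipeline exactly checkable. It does **not** emulate a real
molecule's mode structure, resonance pattern, or orientation-dependent
surface selection rules; passing tests demonstrate the correctness of the
machinery (dressing, differentiation, invariants, factor bookkeeping), not
chemical accuracy for any specific analyte. Absolute AEF/MEF values for
real molecules additionally require quantum-derived tensors.

One consequence worth noting: for anisotropic random tensor sets the
molecular and reflected contributions can interfere destructively, pushing
AEF below 1 at intermediate distances and making its approach to 1
non-monotone. The monotone ~d⁻⁴ decay statement applies to the
electromagnetic channels themselves, so the distance-decay acceptance test
probes them with an isotropic-derivative molecule; the anisotropic trend
test (which also decays for typical seeds) lives in the unit suite.

## Problem sizes

All shipped computations are desk-scale by design: the acceptance
computation solves the 474-atom r = 20 Å disk over a 156-point frequency
scan (seconds); the largest validation runs (3700-atom disks, 3055-atom
spheres) were used once to establish the calibration and convergence
numbers quoted above and are not rerun in the test suite.

## Known limitations

* Classical local response: no nonlocality, no electron spill-out, no
  size quantization — hence the +5% residual on the small graphene disk.
* Chemical (charge-transfer) enhancement is outside the model by
  construction; only the electromagnetic mechanism is described.
* Vibrational frequencies are not shifted by the substrate.
* Quasistatic only: no retardation or radiative damping, so structures
  should stay well below the optical wavelength.
* The shipped interband tables are synthetic one-oscillator stand-ins;
  quantitative metal work should supply experimentally derived tables.
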