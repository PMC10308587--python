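# omegafq

Atomistic, frequency-dependent electromagnetic response of plasmonic
nanostructures — noble-metal clusters and doped graphene disks — with a
classical surface-enhanced Raman scattering (SERS/GERS) calculator on top.

The package is for computational spectroscopists who want to estimate how a
plasmonic substrate reshapes and amplifies the Raman spectrum of a nearby
molecule without running a full quantum-chemistry/substrate coupling: the
substrate is fully atomistic but classical, and the molecule enters through
its (complex) polarizability tensors.

## The models

**ωFQ** endows every substrate atom *i* with a complex oscillating charge
*q<sub>i</sub>*. Charge flows only between conduction neighbors, following
Drude dynamics, and the linear system at frequency ω reads (atomic units,
e<sup>−iωt</sup> convention)

    iω q + z(ω) K (T^qq q + V_ext) = 0,        z(ω) = n0 τ / m*(1 − iωτ)

where `K` is the conduction-network operator with per-bond weights
`f(r_ij) A_ij / r_ij`, `T^qq` the Gaussian-smeared Coulomb kernel, and
`V_ext,i = −E_ext·r_i` the quasistatic external potential. The Fermi-type
damping `f(r_ij)` switches conduction off across sub-nanometer gaps
(quantum-tunneling mimic), and the zero column sums of `K` conserve total
charge exactly. All frequency dependence sits in the scalar `z(ω)` and the
`iω` diagonal shift, so the geometric operators are assembled once per
structure.

**ωFQFμ** adds a complex point dipole μ<sub>i</sub> per atom, driven by the
interband (d-electron) polarizability α<sub>IB</sub>(ω):

    z'(ω) μ − T^μq q − T^μμ μ = E_ext,          z'(ω) = 1 / α_IB(ω)

coupled back into the charge equation through the dipole potentials. For
graphene, the Drude parameters follow from the Fermi energy through the
Dirac dispersion (n<sub>2D</sub> = E<sub>F</sub>²/π v<sub>F</sub>², m* =
E<sub>F</sub>/v<sub>F</sub>²), which makes the disk plasmon tunable by
doping.

**SERS.** The molecule is a point polarizable object at a site near the
substrate. Three substrate operators are computed at the excitation
frequency: the local field `L` (substrate-enhanced driving field at the
site), the back-action `M` (substrate response to the molecular dipole,
iterated to a fixed point) and the emission operator `G` (the reflected part
of the scattered field). The observed dressed tensor

    ᾱ = (1 + G)(1 − α M)⁻¹ α L

is differentiated along each normal mode (central differences, step
0.001 Å) and fed into Placzek theory,

    I_k ∝ (ω − ω_k)⁴ / 2ω_k · (45 α′² + 7 γ′² + 5 δ′²) / 45,

giving per-mode enhancement factors EF<sub>k</sub> = I<sub>PS,k</sub> /
I<sub>vac,k</sub>, their intensity-weighted average AEF, the maximum MEF,
and the volume-averaged E⁴ estimator ⟨|E<sub>tot</sub>|⁴/|E<sub>ext</sub>|⁴⟩
over the molecular box.

## Worked example

Build a 55-atom silver icosahedron, locate its plasmon resonance, and
compute the SERS spectrum of a synthetic three-mode molecule adsorbed 3 Å
above the tip:

```
$ omegafq build --shape icosahedron --shells 2 --element Ag -o ih55.xyz
55 atoms -> ih55.xyz
$ omegafq sers --xyz ih55.xyz --material-id ag --model wfqfmu \
      --omega-at prf --scan-min 2.0 --scan-max 4.5 --pol y -o out --seed 1
{
  "omega_ev": 3.437525040391416,
  "AEF": 2549.3993533193484,
  "MEF": 3284.197040288336,
  "upsilon4_vol": 16333.00333755192
}
```

The excitation lands on the cluster's dipolar plasmon (3.44 eV, silver-like);
the molecule's Raman intensity is amplified by a factor ~2.5·10³ on average
(AEF) and ~3.3·10³ for the most enhanced mode (MEF). `out/sticks.tsv` lists
the per-mode gas-phase and enhanced intensities:

```
# freq_cm   I_vac_au        I_ps_au         EF
600.0000    2.64862495e-01  6.43958230e+02  2.43129263e+03
1100.0000   5.73701788e-02  8.82276764e+01  1.53786651e+03
1600.0000   1.21548916e-01  3.99190590e+02  3.28419704e+03
```

`upsilon4_vol` is the E⁴ estimate of the enhancement averaged over the
molecular box; it exceeds AEF here because the near field decays steeply
across the box. The same pipeline runs on graphene disks
(`--material-id graphene`, `omegafq build --disk --radius 20`), where the
resonance sits in the infrared and is set by the Fermi energy.

As a library:

```python
import numpy as np, omegafq as o

disk = o.build_graphene_disk(20.0)                    # 474 C atoms
mat  = o.graphene(fermi_energy_ev=0.4, structure=disk)
prf, spec = o.scan_prf(disk, mat, 0.2, 0.9,
                       polarization=np.array([1.0, 0, 0]), model="wfq")
print(f"{prf:.3f} eV")                                # 0.642 eV
```

## Layout

- `omegafq.geometry` — cluster/disk builders, neighbor lists, XYZ I/O
- `omegafq.materials` — z(ω), z′(ω), graphene doping, tunneling damping
- `omegafq.response` — assembly and solution of both models, spectra, fields
- `omegafq.sers` — dressing operators, Placzek intensities, EF/AEF/MEF, E⁴
- `omegafq.fixtures` — deterministic toy geometries and synthetic tensors
- `omegafq.config` / `omegafq.cli` — run configuration and the `omegafq` CLI

See `docs/methods.md` for the model assumptions, parameter provenance and
known limitations.
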