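"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` is a plain, explicitly united description of one run:
geometry, material, response model, frequency plan, polarization, molecule
and outputs.  ``run_pipeline`` composes the package end to end — build or
load the substrate, locate the plasmon resonance if asked, dress the
molecular tensors, differentiate along the modes, form Placzek intensities
and enhancement factors, convolve the spectra — and writes every artifact
plus a log recording each default that was taken.  Reruns with the same
configuration and seed are bitwise identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .fixtures import SyntheticRamanSet, generate_synthetic_tensors
from .geometry import build_fcc_cluster, build_graphene_disk, read_xyz, write_xyz
from .materials import get_material, load_material
from .response import scan_prf
from .sers import (
    DEFAULT_BOX_SPACING_ANG,
    DEFAULT_FWHM_CM1,
    compute_sers,
    load_raman_tensors,
)

logger = logging.getLogger("omegafq.pipeline")

#: default PRF coarse-scan windows per material family (eV)
DEFAULT_SCAN_EV = {"graphene": (0.2, 0.9), "metal": (2.0, 6.0)}


@dataclass
class RunConfig:
    """Declarative description of one SERS run (units in the field names)."""

    # geometry: either a builder spec or an xyz file
    geometry_shape: str | None = None       # icosahedron/cuboctahedron/ino_decahedron/disk
    geometry_shells: int = 2
    geometry_element: str = "Ag"
    geometry_radius_ang: float = 20.0       # disk only
    geometry_xyz: str | None = None

    material_id: str | None = None          # ag / au / graphene
    material_file: str | None = None
    fermi_energy_ev: float = 0.4            # graphene only

    model: str = "wfq"                      # wfq | wfqfmu

    frequency_mode: str = "at_prf"          # at_prf | fixed
    omega_ev: float | None = None           # fixed mode
    scan_min_ev: float | None = None
    scan_max_ev: float | None = None

    polarization: tuple = (0.0, 1.0, 0.0)

    molecule_tensors: str | None = None     # file path; None -> synthetic set
    molecule_n_modes: int = 3
    molecule_site: tuple | None = None      # explicit site (angstrom)
    molecule_distance_ang: float = 3.0      # else: along +y above the tip
    box_spacing_ang: float = DEFAULT_BOX_SPACING_ANG
    fwhm_cm1: float = DEFAULT_FWHM_CM1
    reflected_field: bool = True
    include_substrate: bool = True

    output_dir: str = "omegafq_out"
    seed: int = 0

    def to_yaml(self, path=None):
        def plain(v):
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v

        doc = {k: plain(v) for k, v in asdict(self).items()}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text):
        s = str(path_or_text)
        if "\n" not in s and Path(s).exists():
            text = Path(s).read_text()
        else:
            text = s
        doc = yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.polarization = tuple(cfg.polarization)
        if cfg.molecule_site is not None:
            cfg.molecule_site = tuple(cfg.molecule_site)
        return cfg


def _build_structure(cfg):
    if cfg.geometry_xyz is not None:
        logger.info("geometry: reading %s", cfg.geometry_xyz)
        return read_xyz(cfg.geometry_xyz)
    if cfg.geometry_shape is None:
        return None
    if cfg.geometry_shape == "disk":
        logger.info("geometry: graphene disk r = %.2f A", cfg.geometry_radius_ang)
        return build_graphene_disk(cfg.geometry_radius_ang)
    logger.info("geometry: %s cluster, %d shells, %s",
                cfg.geometry_shape, cfg.geometry_shells, cfg.geometry_element)
    return build_fcc_cluster(cfg.geometry_shape, cfg.geometry_shells,
                             element=cfg.geometry_element)


def _build_material(cfg, structure):
    if cfg.material_file is not None:
        return load_material(cfg.material_file)
    mat_id = cfg.material_id
    if mat_id is None and structure is not None:
        mat_id = structure.material_id
    if mat_id is None:
        return None
    if mat_id.lower() == "graphene":
        logger.info("material: graphene, E_F = %.3f eV (default parameterization)",
                    cfg.fermi_energy_ev)
        return get_material("graphene", fermi_energy_ev=cfg.fermi_energy_ev,
                            structure=structure)
    logger.info("material: %s (default parameterization)", mat_id)
    return get_material(mat_id)


def _molecule_site(cfg, structure):
    if cfg.molecule_site is not None:
        return np.asarray(cfg.molecule_site, float)
    if structure is None or structure.n_atoms == 0:
        return np.zeros(3)
    y_top = float(structure.positions[:, 1].max())
    site = np.array([0.0, y_top + cfg.molecule_distance_ang, 0.0])
    logger.info("molecule: placed %.2f A above the +y tip at %s",
                cfg.molecule_distance_ang, np.round(site, 3).tolist())
    return site


def _resolve_omega(cfg, structure, material):
    if cfg.frequency_mode == "fixed":
        if cfg.omega_ev is None:
            raise ConfigurationError("fixed frequency mode requires omega_ev")
        return float(cfg.omega_ev), None
    if cfg.frequency_mode != "at_prf":
        raise ConfigurationError(f"unknown frequency_mode {cfg.frequency_mode!r}")
    if structure is None:
        raise ConfigurationError("at_prf frequency mode requires a substrate")
    fam = "graphene" if material.name == "graphene" else "metal"
    lo = cfg.scan_min_ev if cfg.scan_min_ev is not None else DEFAULT_SCAN_EV[fam][0]
    hi = cfg.scan_max_ev if cfg.scan_max_ev is not None else DEFAULT_SCAN_EV[fam][1]
    logger.info("frequency: locating PRF in [%.2f, %.2f] eV", lo, hi)
    prf, spectrum = scan_prf(structure, material, lo, hi,
                             polarization=cfg.polarization, model=cfg.model)
    logger.info("frequency: PRF = %.4f eV", prf)
    return prf, spectrum


def run_pipeline(config, write_artifacts=True):
    """Execute the configured SERS run; returns the :class:`SERSResult`."""
    cfg = config
    out = Path(cfg.output_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
        root = logging.getLogger("omegafq")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    try:
        logger.info("omegafq version %s, seed %d", __version__, cfg.seed)
        structure = _build_structure(cfg) if cfg.include_substrate else None
        material = _build_material(cfg, structure)
        site = _molecule_site(cfg, structure)
        if cfg.molecule_tensors is not None:
            molecule = load_raman_tensors(cfg.molecule_tensors)
            molecule.site = site
            molecule.box = None
            molecule.__post_init__()
        else:
            logger.info("molecule: synthetic %d-mode tensor set (seed %d)",
                        cfg.molecule_n_modes, cfg.seed)
            spec = SyntheticRamanSet(n_modes=cfg.molecule_n_modes,
                                     site=tuple(site))
            molecule = generate_synthetic_tensors(spec, cfg.seed)
        if structure is not None and material is not None:
            omega, _ = _resolve_omega(cfg, structure, material)
        else:
            omega = float(cfg.omega_ev) if cfg.omega_ev is not None else 1.0
            logger.info("gas phase run at omega = %.4f eV", omega)
        result = compute_sers(
            structure, material, molecule, omega, model=cfg.model,
            polarization=cfg.polarization, reflected=cfg.reflected_field,
            box_spacing_ang=cfg.box_spacing_ang, fwhm_cm1=cfg.fwhm_cm1,
            with_upsilon=structure is not None,
        )
        result.extras["seed"] = cfg.seed
        result.extras["model"] = cfg.model
        if write_artifacts:
            _write_artifacts(cfg, structure, result, out)
        return result
    finally:
        if write_artifacts:
            root.removeHandler(handler)
            handler.close()


def _write_artifacts(cfg, structure, result, out):
    cfg.to_yaml(out / "resolved_config.yaml")
    if structure is not None:
        write_xyz(structure, out / "substrate.xyz")
    with open(out / "sticks.tsv", "w") as fh:
        fh.write("# freq_cm\tI_vac_au\tI_ps_au\tEF\n")
        for f, iv, ip, ef in zip(result.mode_freqs_cm, result.intensity_vac,
                                 result.intensity_ps, result.ef):
            fh.write(f"{f:.4f}\t{iv:.8e}\t{ip:.8e}\t{ef:.8e}\n")
    with open(out / "spectrum.tsv", "w") as fh:
        fh.write("# raman_shift_cm\tI_vac_au\tI_ps_au\n")
        for g, sv, sp in zip(result.spectrum_grid_cm, result.spectrum_vac,
                             result.spectrum_ps):
            fh.write(f"{g:.4f}\t{sv:.8e}\t{sp:.8e}\n")
    report = {
        "omega_ev": result.omega_ev,
        "aef": result.aef,
        "mef": result.mef,
        "upsilon4_vol": result.upsilon4,
        "n_modes": int(len(result.mode_freqs_cm)),
        "seed": cfg.seed,
        "model": cfg.model,
        "version": __version__,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("artifacts written to %s", out)
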