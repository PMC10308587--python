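"""Atomistic substrate geometries: fcc metal clusters and graphene disks.

Builders return :class:`Nanostructure` objects whose neighbor lists define the
conduction network of the frequency-dependent fluctuating-charge response
models.  Conventions:

* coordinates in angstrom, centered on the cluster/disk center;
* the principal symmetry axis (adsorption axis) is aligned with ``y`` — metal
  clusters expose a vertex along ``+y``, graphene disks lie in the ``xz``
  plane with their normal along ``y``;
* conduction neighbors are pairs within ``cutoff_factor`` times the
  first-neighbor distance (1.2 for close-packed metals, 1.1 for graphene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, GeometryError, ParseError

#: Default fcc lattice constants (angstrom).
LATTICE_CONSTANTS = {"Ag": 4.09, "Au": 4.08}

#: Default graphene C-C bond length (angstrom).
CC_BOND = 1.42

MIN_INTERATOMIC_DISTANCE = 0.5  # angstrom, degenerate-geometry guard

METAL_CUTOFF_FACTOR = 1.2
GRAPHENE_CUTOFF_FACTOR = 1.1


@dataclass
class Nanostructure:
    """Atom positions plus the conduction neighbor list.

    Parameters
    ----------
    positions : (N, 3) float array, angstrom
    elements : length-N list of chemical symbols
    material_id : key into a material registry (may be None until binding)
    neighbor_cutoff : angstrom; pairs closer than this exchange charge
    """

    positions: np.ndarray
    elements: list
    material_id: str | None = None
    neighbor_cutoff: float | None = None
    pairs: np.ndarray = field(init=False)          # (M, 2) int, i < j
    pair_distances: np.ndarray = field(init=False)  # (M,) angstrom

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if len(self.elements) != n:
            raise GeometryError("elements and positions lengths differ")
        if n >= 2:
            tree = cKDTree(self.positions)
            d, _ = tree.query(self.positions, k=2)
            dmin = float(d[:, 1].min())
            if dmin < MIN_INTERATOMIC_DISTANCE:
                raise GeometryError(
                    f"atoms closer than {MIN_INTERATOMIC_DISTANCE} A (min {dmin:.3f} A)"
                )
            if self.neighbor_cutoff is None:
                self.neighbor_cutoff = METAL_CUTOFF_FACTOR * dmin
            pairs = tree.query_pairs(self.neighbor_cutoff, output_type="ndarray")
            pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
            self.pairs = pairs
            diff = self.positions[pairs[:, 0]] - self.positions[pairs[:, 1]]
            self.pair_distances = np.linalg.norm(diff, axis=1)
        else:
            self.pairs = np.empty((0, 2), dtype=int)
            self.pair_distances = np.empty(0)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def neighbor_list(self):
        """Symmetric neighbor list: (i, j, r_ij) for both orderings."""
        for (i, j), r in zip(self.pairs, self.pair_distances):
            yield int(i), int(j), float(r)
            yield int(j), int(i), float(r)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=int)
        for i, j in self.pairs:
            deg[i] += 1
            deg[j] += 1
        return deg

    def first_neighbor_distance(self) -> float:
        if len(self.pair_distances) == 0:
            raise GeometryError("structure has no bonded pairs")
        return float(self.pair_distances.min())


def _rotation_onto(u, v):
    """Rotation matrix taking unit vector u onto unit vector v."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    c = float(u @ v)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any axis orthogonal to u
        a = np.eye(3)[np.argmin(np.abs(u))]
        a = a - (a @ u) * u
        a /= np.linalg.norm(a)
        return 2 * np.outer(a, a) - np.eye(3)
    a = np.cross(u, v)
    s = np.linalg.norm(a)
    a /= s
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _dedupe(points, tol=1e-6):
    points = np.asarray(points, float)
    keys = np.round(points / tol).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return points[np.sort(idx)]


def _icosahedron_vertices():
    phi = (1 + np.sqrt(5)) / 2
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(v)
    return v / np.linalg.norm(v[0])


def _icosahedron_faces(verts):
    # faces = triples of mutually nearest vertices
    edge = np.min(
        [np.linalg.norm(verts[0] - verts[j]) for j in range(1, len(verts))]
    )
    faces = []
    n = len(verts)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(verts[i] - verts[j]) > edge * 1.01:
                continue
            for k in range(j + 1, n):
                if (
                    np.linalg.norm(verts[i] - verts[k]) <= edge * 1.01
                    and np.linalg.norm(verts[j] - verts[k]) <= edge * 1.01
                ):
                    faces.append((i, j, k))
    return faces


def _build_icosahedron(n_shells, d_nn):
    """Mackay icosahedron; radial (center-vertex) spacing equals d_nn."""
    verts = _icosahedron_vertices() * d_nn
    faces = _icosahedron_faces(verts)
    pts = [np.zeros(3)]
    for s in range(1, n_shells + 1):
        for (ia, ib, ic) in faces:
            a, b, c = verts[ia], verts[ib], verts[ic]
            for i in range(s + 1):
                for j in range(s + 1 - i):
                    k = s - i - j
                    pts.append(i * a + j * b + k * c)
    pts = _dedupe(np.array(pts))
    # vertex along +y
    R = _rotation_onto(verts[0] / np.linalg.norm(verts[0]), (0, 1, 0))
    return pts @ R.T


def _build_cuboctahedron(n_shells, lattice_constant):
    """fcc cuboctahedron: cube cut |i|,|j|,|k| <= k and octahedron cut
    |i|+|j|+|k| <= 2k on the fcc lattice (units of a/2)."""
    k = n_shells
    g = np.arange(-k, k + 1)
    I, J, K = np.meshgrid(g, g, g, indexing="ij")
    sel = ((I + J + K) % 2 == 0) & (np.abs(I) + np.abs(J) + np.abs(K) <= 2 * k)
    pts = np.stack([I[sel], J[sel], K[sel]], axis=-1) * (lattice_constant / 2.0)
    # vertex of the cuboctahedron is a <110> direction; expose it along +y
    R = _rotation_onto((1, 1, 0), (0, 1, 0))
    return pts @ R.T


def _build_ino_decahedron(n_shells, d_nn):
    """Pentagonal decahedron: five slightly strained fcc tetrahedra sharing
    the five-fold (y) axis; for n_shells >= 3 the apexes are truncated
    (Ino-style (100) facets)."""
    n = n_shells
    s_pent = n * d_nn
    Rq = s_pent / (2 * np.sin(np.pi / 5))
    h = np.sqrt(max(s_pent**2 - Rq**2, 0.0))
    T = np.array([0.0, h, 0.0])
    B = -T
    E = [
        np.array([Rq * np.cos(2 * np.pi * k / 5), 0.0, Rq * np.sin(2 * np.pi * k / 5)])
        for k in range(5)
    ]
    pts = []
    for k in range(5):
        va, vb, vc, vd = T, B, E[k], E[(k + 1) % 5]
        for i in range(n + 1):
            for j in range(n + 1 - i):
                for l in range(n + 1 - i - j):
                    m = n - i - j - l
                    pts.append((i * va + j * vb + l * vc + m * vd) / n)
    pts = _dedupe(np.array(pts))
    t = n // 3  # apex layers removed (0 for small clusters)
    if t:
        ycut = h * (n - t) / n + 1e-9
        pts = pts[np.abs(pts[:, 1]) <= ycut]
    return pts


FCC_SHAPES = {
    "cuboctahedron": _build_cuboctahedron,
    "icosahedron": _build_icosahedron,
    "ino_decahedron": _build_ino_decahedron,
}


def build_fcc_cluster(shape, n_shells, lattice_constant=None, element="Ag"):
    """Build a closed-shell metal cluster centered at the origin.

    ``shape`` is one of ``cuboctahedron``, ``icosahedron``,
    ``ino_decahedron``; ``n_shells`` counts closed geometric shells.  The
    adsorption vertex (or five-fold axis) points along ``+y``.
    """
    if shape not in FCC_SHAPES:
        raise ConfigurationError(
            f"unknown cluster shape {shape!r}; expected one of {sorted(FCC_SHAPES)}"
        )
    if n_shells < 1:
        raise ConfigurationError("n_shells must be >= 1")
    if lattice_constant is None:
        try:
            lattice_constant = LATTICE_CONSTANTS[element]
        except KeyError:
            raise ConfigurationError(
                f"no default lattice constant for element {element!r}"
            ) from None
    if lattice_constant <= 0:
        raise ConfigurationError("lattice_constant must be positive")
    d_nn = lattice_constant / np.sqrt(2.0)
    if shape == "cuboctahedron":
        pts = _build_cuboctahedron(n_shells, lattice_constant)
    elif shape == "icosahedron":
        pts = _build_icosahedron(n_shells, d_nn)
    else:
        pts = _build_ino_decahedron(n_shells, d_nn)
    cutoff = METAL_CUTOFF_FACTOR * d_nn
    return Nanostructure(
        pts, [element] * len(pts), material_id=element.lower(), neighbor_cutoff=cutoff
    )


def build_graphene_disk(radius, cc_bond=CC_BOND):
    """Cut a circular disk from a graphene sheet and prune dangling bonds.

    The disk lies in the ``xz`` plane (normal along ``y``) and is centered on
    a hexagon center, so the disk center of mass is not an atom.  Atoms with
    fewer than two lattice neighbors are removed iteratively until every
    retained atom has at least two.
    """
    if radius < 2 * cc_bond:
        raise GeometryError(
            f"radius {radius} A too small to contain a hexagon (need >= {2 * cc_bond} A)"
        )
    d = cc_bond
    a1 = np.array([1.5 * d, np.sqrt(3) / 2 * d])
    a2 = np.array([1.5 * d, -np.sqrt(3) / 2 * d])
    basis = [np.zeros(2), np.array([d, 0.0])]
    shift = np.array([d / 2, np.sqrt(3) / 2 * d])  # hexagon center -> origin
    nmax = int(radius / d) + 3
    pts = []
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            for b in basis:
                p = i * a1 + j * a2 + b - shift
                if p @ p <= radius * radius:
                    pts.append(p)
    pts = np.array(pts)
    # iterative dangling-bond removal to fixpoint
    while len(pts):
        tree = cKDTree(pts)
        prs = tree.query_pairs(d * GRAPHENE_CUTOFF_FACTOR, output_type="ndarray")
        deg = np.zeros(len(pts), dtype=int)
        for i, j in prs:
            deg[i] += 1
            deg[j] += 1
        keep = deg >= 2
        if keep.all():
            break
        pts = pts[keep]
    if len(pts) < 6:
        raise GeometryError("no complete hexagon fits inside the requested radius")
    xyz = np.zeros((len(pts), 3))
    xyz[:, 0] = pts[:, 0]
    xyz[:, 2] = pts[:, 1]
    return Nanostructure(
        xyz,
        ["C"] * len(xyz),
        material_id="graphene",
        neighbor_cutoff=GRAPHENE_CUTOFF_FACTOR * cc_bond,
    )


def read_xyz(path, material_id=None, neighbor_cutoff=None):
    """Read a plain XYZ file (count line, comment line, ``El x y z`` rows)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty file", line=1)
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"malformed atom count {lines[0]!r}", line=1) from None
    if len(lines) < 2 + count:
        raise ParseError(
            f"expected {count} atom lines, found {max(len(lines) - 2, 0)}",
            line=len(lines) + 1,
        )
    elements, pos = [], []
    for ln in range(2, 2 + count):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"expected 'El x y z', got {lines[ln]!r}", line=ln + 1)
        try:
            pos.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ParseError(
                f"non-numeric coordinate in {lines[ln]!r}", line=ln + 1
            ) from None
        elements.append(parts[0])
    return Nanostructure(
        np.array(pos), elements, material_id=material_id, neighbor_cutoff=neighbor_cutoff
    )


def write_xyz(structure, path, comment="generated by omegafq"):
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{comment}\n")
        for el, p in zip(structure.elements, structure.positions):
            fh.write(f"{el} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")
    return path
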