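"""Nanostructure geometries and neighbor graphs.

Generators for the two substrate families used throughout the library —
closed-shell Mackay (fcc-twinned) icosahedral metal clusters and circular
graphene disks cut from the pristine honeycomb lattice — plus a KD-tree
neighbor graph and standard XYZ input/output.

Positions are stored in Å; conversion to atomic units happens inside the
response machinery, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "NanoStructure",
    "mackay_magic_number",
    "build_mackay_icosahedron",
    "build_graphene_disk",
    "neighbor_graph",
    "read_xyz",
    "write_xyz",
]


class XYZParseError(ValueError):
    """Malformed XYZ file; message names the offending line number."""


@dataclass
class NanoStructure:
    """Atomistic substrate geometry with an optional neighbor graph.

    Attributes
    ----------
    positions : (N, 3) float array, Å
    labels : (N,) array of element/material tags
    pairs : (M, 2) int array of neighbor pairs with i < j; the neighbor
        relation is understood as symmetric, (i, j) stands for both
        directed pairs.
    pair_distances : (M,) float array, Å, Euclidean distances of `pairs`
    material_id : key naming the material parameter set for this structure
    """

    positions: np.ndarray
    labels: np.ndarray
    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    pair_distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    material_id: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=object)
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        self.pair_distances = np.asarray(self.pair_distances, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def symmetric_pairs(self):
        """Neighbor pairs as a symmetric (2M, 2) array: (i,j) and (j,i)."""
        return np.vstack([self.pairs, self.pairs[:, ::-1]])

    def min_distance(self) -> float:
        """Minimum interatomic distance (Å) over all atom pairs."""
        if self.n_atoms < 2:
            return math.inf
        tree = cKDTree(self.positions)
        d, _ = tree.query(self.positions, k=2)
        return float(d[:, 1].min())

    def validate(self, tol: float = 1e-10) -> None:
        """Raise ValueError if any NanoStructure invariant is violated."""
        if self.n_atoms != len(self.labels):
            raise ValueError("positions and labels length mismatch")
        if self.n_atoms >= 2 and self.min_distance() <= 0.5:
            raise ValueError("overlapping atoms: minimum distance <= 0.5 Å")
        if len(self.pairs):
            if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
                raise ValueError("self-pairs present in neighbor graph")
            d = np.linalg.norm(
                self.positions[self.pairs[:, 0]] - self.positions[self.pairs[:, 1]],
                axis=1,
            )
            if np.max(np.abs(d - self.pair_distances)) > tol:
                raise ValueError("stored pair distances disagree with positions")


def mackay_magic_number(k: int) -> int:
    """Atom count of the closed-shell Mackay icosahedron with k shells."""
    return (10 * k**3 + 15 * k**2 + 11 * k + 3) // 3


def _icosahedron_vertices() -> np.ndarray:
    """The 12 icosahedron vertices scaled to unit edge length."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v.append((0.0, a, b))
            v.append((a, b, 0.0))
            v.append((b, 0.0, a))
    return np.array(v) / 2.0  # raw edge length is 2


def _icosahedron_faces(verts: np.ndarray):
    """The 20 triangular faces as vertex index triples (adjacency by edge)."""
    n = len(verts)
    edge = 1.0  # unit-edge vertices
    faces = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(np.linalg.norm(verts[i] - verts[j]) - edge) > 1e-9:
                continue
            for k in range(j + 1, n):
                if (
                    abs(np.linalg.norm(verts[i] - verts[k]) - edge) < 1e-9
                    and abs(np.linalg.norm(verts[j] - verts[k]) - edge) < 1e-9
                ):
                    faces.append((i, j, k))
    assert len(faces) == 20
    return faces


def build_mackay_icosahedron(
    shells: int, nn_distance: float = 2.885, label: str = "Au", material_id: str = "gold"
) -> NanoStructure:
    """Closed-shell Mackay icosahedral cluster.

    Shell ``j`` places points ``(n1·Va + n2·Vb + n3·Vc)·nn_distance`` with
    ``n1+n2+n3 = j`` on each of the 20 faces of a unit-edge icosahedron, so
    the intra-shell nearest-neighbor distance equals ``nn_distance`` exactly
    (the radial spacing is ~5% shorter — the hallmark Mackay compression).
    The atom count is the icosahedral magic number (10k³+15k²+11k+3)/3.

    Parameters
    ----------
    shells : number of complete shells around the central atom (k ≥ 0)
    nn_distance : intra-shell nearest-neighbor distance in Å
        (2.885 Å = bulk gold)
    """
    if shells < 0:
        raise ValueError("shells must be non-negative")
    if nn_distance <= 0:
        raise ValueError("nn_distance must be positive")
    verts = _icosahedron_vertices()
    faces = _icosahedron_faces(verts)

    points = [np.zeros(3)]
    for j in range(1, shells + 1):
        # barycentric integer grid on each face of the shell-j icosahedron
        n1, n2 = np.meshgrid(np.arange(j + 1), np.arange(j + 1), indexing="ij")
        mask = n1 + n2 <= j
        n1, n2 = n1[mask], n2[mask]
        n3 = j - n1 - n2
        coeffs = np.stack([n1, n2, n3], axis=1).astype(float)
        for (a, b, c) in faces:
            tri = verts[[a, b, c]]
            points.append(coeffs @ tri)
    pos = np.vstack(points) * nn_distance

    # deduplicate shared edge/vertex points
    key = np.round(pos / (1e-6 * nn_distance)).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    pos = pos[np.sort(idx)]

    expected = mackay_magic_number(shells)
    if len(pos) != expected:  # pragma: no cover - construction guarantee
        raise RuntimeError(
            f"Mackay construction produced {len(pos)} atoms, expected {expected}"
        )
    pos -= pos.mean(axis=0)
    return NanoStructure(pos, np.array([label] * len(pos)), material_id=material_id)


def build_graphene_disk(
    diameter_nm: float, cc_bond: float = 1.42, material_id: str = "graphene"
) -> NanoStructure:
    """Circular disk cut from the pristine graphene honeycomb lattice.

    The disk center sits at a hexagon center and an atom is included iff its
    distance from the center is ≤ diameter/2 (atom-center cutting
    convention). The disk lies in the z = 0 plane.

    Parameters
    ----------
    diameter_nm : disk diameter in nm
    cc_bond : carbon–carbon bond length in Å (default 1.42)
    """
    if cc_bond <= 0:
        raise ValueError("cc_bond must be positive")
    radius = diameter_nm * 10.0 / 2.0  # Å
    if radius <= cc_bond:
        raise ValueError("diameter must exceed 2·cc_bond")

    a = cc_bond
    a1 = np.array([math.sqrt(3.0) * a, 0.0])
    a2 = np.array([math.sqrt(3.0) * a / 2.0, 1.5 * a])
    basis = np.array([[0.0, 0.0], [0.0, a]])
    center = np.array([math.sqrt(3.0) * a / 2.0, a / 2.0])  # hexagon center

    # generous index window covering the disk
    nmax = int(radius / a) + 3
    n1, n2 = np.meshgrid(np.arange(-nmax, nmax + 1), np.arange(-nmax, nmax + 1),
                         indexing="ij")
    cells = n1.ravel()[:, None] * a1 + n2.ravel()[:, None] * a2
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 2) - center
    keep = np.einsum("ij,ij->i", pts, pts) <= radius**2
    pts = pts[keep]

    pos = np.zeros((len(pts), 3))
    pos[:, :2] = pts
    return NanoStructure(pos, np.array(["C"] * len(pts)), material_id=material_id)


def neighbor_graph(structure: NanoStructure, cutoff: float) -> NanoStructure:
    """Populate the neighbor graph with all pairs at distance ≤ cutoff (Å).

    Returns the same structure with `pairs`/`pair_distances` replaced.
    Self-pairs are excluded; the stored (i<j) pairs represent the symmetric
    relation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(structure.positions)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    if len(raw):
        raw = raw[np.lexsort((raw[:, 1], raw[:, 0]))]
        d = np.linalg.norm(
            structure.positions[raw[:, 0]] - structure.positions[raw[:, 1]], axis=1
        )
    else:
        raw = np.empty((0, 2), dtype=np.intp)
        d = np.empty(0)
    structure.pairs = raw
    structure.pair_distances = d
    return structure


def write_xyz(structure: NanoStructure, path, comment: str = "") -> None:
    """Write a standard XYZ file (coordinates in Å)."""
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n")
        fh.write(comment.replace("\n", " ") + "\n")
        for lab, (x, y, z) in zip(structure.labels, structure.positions):
            fh.write(f"{lab} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path, material_id: str = "") -> NanoStructure:
    """Read a standard XYZ file (count line, comment line, element x y z)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError("line 1: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"line 1: malformed atom count {lines[0]!r}") from None
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) != count:
        raise XYZParseError(
            f"line 1: header declares {count} atoms but file has {len(records)} records"
        )
    labels, pos = [], []
    for k, ln in enumerate(records):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"line {k + 3}: expected 'element x y z', got {ln!r}")
        try:
            pos.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise XYZParseError(f"line {k + 3}: non-numeric coordinate in {ln!r}") from None
        labels.append(parts[0])
    return NanoStructure(np.array(pos), np.array(labels), material_id=material_id)
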