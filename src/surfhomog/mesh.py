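"""Triangulated spherical meshes and ring-neighborhood tables.

The spatial domain of every map in this package is a subdivided icosahedron
("icosphere") standing in for a registered spherical cortical surface such as
FreeSurfer's fsaverage5 (order 5: 10,242 vertices per hemisphere).  Local
neighborhoods are defined by graph distance on the triangulation — the
standard convention for surface-based regional homogeneity — not by Euclidean
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SphereMesh",
    "NeighborTable",
    "build_icosphere",
    "ring_neighbors",
    "build_neighbor_table",
    "read_surface",
    "write_surface",
]

MAX_SUBDIVISION_ORDER = 7

# Icosahedron with the golden-ratio construction; vertex order is fixed so
# every downstream index is reproducible.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


@dataclass
class SphereMesh:
    """A closed triangulated sphere.

    Attributes
    ----------
    vertices : (V, 3) float array, unit-sphere coordinates.
    faces : (F, 3) int array of vertex-index triples.
    subdivision_order : number of 1-to-4 subdivisions applied to the
        icosahedron; V = 10·4**order + 2.
    """

    vertices: np.ndarray
    faces: np.ndarray
    subdivision_order: int
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False)
    _edges: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) array with u < v."""
        if self._edges is None:
            f = self.faces
            e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            e = np.sort(e, axis=1)
            self._edges = np.unique(e, axis=0)
        return self._edges

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Boolean vertex adjacency (V × V, symmetric, zero diagonal)."""
        if self._adjacency is None:
            e = self.edges
            v = self.n_vertices
            data = np.ones(2 * e.shape[0], dtype=np.int8)
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._adjacency = sp.csr_matrix((data, (rows, cols)), shape=(v, v))
        return self._adjacency

    def vertex_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def validate(self) -> None:
        """Assert the closed-2-manifold invariants; raise ValueError if violated."""
        v, f, e = self.n_vertices, self.n_faces, self.n_edges
        if v - e + f != 2:
            raise ValueError(f"Euler characteristic V-E+F = {v - e + f}, expected 2")
        # every undirected edge must appear in exactly two faces
        fa = self.faces
        halfedges = np.concatenate([fa[:, [0, 1]], fa[:, [1, 2]], fa[:, [2, 0]]])
        halfedges = np.sort(halfedges, axis=1)
        _, counts = np.unique(halfedges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("mesh is not a closed 2-manifold (edge shared by != 2 faces)")
        deg = self.vertex_degrees()
        if np.sum(deg == 5) != 12 or not np.all(np.isin(deg, (5, 6))):
            raise ValueError("icosphere degree structure violated (expect 12 degree-5 vertices)")


def build_icosphere(order: int) -> SphereMesh:
    """Subdivide the icosahedron ``order`` times, projecting onto the unit sphere.

    Midpoint vertices are indexed in deterministic order of first encounter
    (faces scanned in index order, edges keyed by sorted endpoint pair), so a
    given order always yields bit-identical vertex coordinates and faces.

    Parameters
    ----------
    order : subdivision depth, 0 ≤ order ≤ 7.  Order 5 matches fsaverage5's
        10,242 vertices per hemisphere.
    """
    if not isinstance(order, (int, np.integer)):
        raise TypeError(f"order must be an integer, got {type(order).__name__}")
    if order < 0 or order > MAX_SUBDIVISION_ORDER:
        raise ValueError(f"order must be in [0, {MAX_SUBDIVISION_ORDER}], got {order}")

    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()

    for _ in range(order):
        verts, faces = _subdivide(verts, faces)

    return SphereMesh(vertices=verts, faces=faces, subdivision_order=int(order))


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    new_verts = [v for v in verts]
    midpoint: dict[tuple[int, int], int] = {}

    def mid(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = midpoint.get(key)
        if idx is None:
            p = verts[a] + verts[b]
            p = p / np.linalg.norm(p)
            idx = len(new_verts)
            new_verts.append(p)
            midpoint[key] = idx
        return idx

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for i, (a, b, c) in enumerate(faces):
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces[4 * i: 4 * i + 4] = [
            [a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca],
        ]
    return np.array(new_verts), new_faces


def ring_neighbors(
    mesh: SphereMesh, vertex: int, ring_order: int = 1, include_center: bool = False
) -> np.ndarray:
    """Vertices at graph distance 1..ring_order from ``vertex``.

    Returns indices sorted ascending; when ``include_center`` the center vertex
    comes first.  Pure function of the triangulation.
    """
    if ring_order not in (1, 2):
        raise ValueError(f"ring_order must be 1 or 2, got {ring_order}")
    v = int(vertex)
    if v < 0 or v >= mesh.n_vertices:
        raise IndexError(f"vertex {vertex} out of range [0, {mesh.n_vertices})")
    adj = mesh.adjacency
    ring = set(adj.indices[adj.indptr[v]: adj.indptr[v + 1]].tolist())
    if ring_order == 2:
        second = set()
        for u in ring:
            second.update(adj.indices[adj.indptr[u]: adj.indptr[u + 1]].tolist())
        ring |= second
        ring.discard(v)
    out = np.array(sorted(ring), dtype=np.int64)
    if include_center:
        out = np.concatenate([[v], out])
    return out


@dataclass
class NeighborTable:
    """Closed ring neighborhoods (center first) for every vertex of a mesh.

    ``neighborhoods[v]`` lists v followed by all vertices at graph distance
    ≤ ring_order, ascending.  ``K_per_vertex[v]`` is its length: 7 at
    degree-6 vertices and 6 at the 12 degree-5 vertices for ring 1; 19 at
    interior vertices (two-ring free of degree-5 vertices) for ring 2.
    """

    ring_order: int
    neighborhoods: list[np.ndarray]
    K_per_vertex: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.neighborhoods)

    def closed_indicator(self) -> sp.csr_matrix:
        """Sparse (V × V) 0/1 matrix; row v marks v's closed neighborhood."""
        indptr = np.concatenate([[0], np.cumsum(self.K_per_vertex)])
        indices = np.concatenate(self.neighborhoods)
        data = np.ones(indices.shape[0], dtype=np.float64)
        v = self.n_vertices
        return sp.csr_matrix((data, indices, indptr), shape=(v, v))


def build_neighbor_table(mesh: SphereMesh, ring_order: int = 1) -> NeighborTable:
    if ring_order not in (1, 2):
        raise ValueError(f"ring_order must be 1 or 2, got {ring_order}")
    adj = mesh.adjacency
    reach = adj if ring_order == 1 else (adj @ adj + adj)
    reach = reach.tocsr()
    neighborhoods = []
    for v in range(mesh.n_vertices):
        nb = reach.indices[reach.indptr[v]: reach.indptr[v + 1]]
        nb = np.setdiff1d(nb, [v])  # setdiff1d sorts ascending
        neighborhoods.append(np.concatenate([[v], nb]).astype(np.int64))
    k = np.array([len(nb) for nb in neighborhoods], dtype=np.int64)
    return NeighborTable(ring_order=ring_order, neighborhoods=neighborhoods, K_per_vertex=k)


# ---------------------------------------------------------------------------
# Surface I/O: FreeSurfer binary geometry and GIFTI .surf.gii, so real
# registered spheres can replace the generated icosphere.

def write_surface(path: str, mesh: SphereMesh) -> None:
    import nibabel as nib

    path = str(path)
    if path.endswith(".gii"):
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            )
        )
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            )
        )
        nib.save(img, path)
    else:
        nib.freesurfer.write_geometry(path, mesh.vertices, mesh.faces)


def read_surface(path: str) -> SphereMesh:
    import nibabel as nib

    path = str(path)
    if path.endswith(".gii"):
        img = nib.load(path)
        verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data.astype(float)
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data.astype(np.int64)
    else:
        verts, faces = nib.freesurfer.read_geometry(path)
        verts = np.asarray(verts, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
    n = verts.shape[0]
    # infer order from the closed-form count when it matches
    order = -1
    for k in range(MAX_SUBDIVISION_ORDER + 1):
        if n == 10 * 4**k + 2:
            order = k
            break
    return SphereMesh(vertices=verts, faces=faces, subdivision_order=order)
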