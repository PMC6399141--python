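"""Synthetic heart / torso-tank geometry and electrode placement.

Surfaces are analytic ellipsoids triangulated by icosahedron subdivision;
the alignment and inverse algorithms downstream are geometry-generic, so
anatomical realism is deliberately not attempted.  Units are mm throughout,
right-handed world frame, heart centroid near the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ecgitank.errors import ContainmentError, InvalidParameterError

__all__ = [
    "TriMesh",
    "ElectrodeSet",
    "make_heart_mesh",
    "make_torso_tank",
    "place_electrodes",
    "icosphere",
]


@dataclass
class TriMesh:
    """Closed triangulated surface.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices, outward CCW winding
    vertex_normals : (n, 3) float array, outward unit normals
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise InvalidParameterError("faces index invalid vertices")
        if self.vertex_normals is None:
            self.vertex_normals = _vertex_normals(self.vertices, self.faces)
        else:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) sorted-index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def is_closed(self) -> bool:
        """Every undirected edge shared by exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def validate(self) -> None:
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise InvalidParameterError("faces index invalid vertices")
        if np.any(self.face_areas() <= 0):
            raise InvalidParameterError("degenerate (zero-area) face present")
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidParameterError("vertex normals are not unit length")
        if not self.is_closed():
            raise InvalidParameterError("surface is not closed")

    def adjacency(self):
        """Sparse symmetric vertex adjacency weighted by edge length."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.concatenate([w, w])
        return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


@dataclass
class ElectrodeSet:
    """Electrodes snapped to mesh vertices.

    positions coincide with their host vertices by construction; ``valid``
    marks channels usable for recording/inversion.
    """

    positions: np.ndarray
    labels: list
    host_vertex: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.host_vertex = np.asarray(self.host_vertex, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(set(self.labels)) != len(self.labels):
            raise InvalidParameterError("electrode labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "host_vertex": self.host_vertex,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ElectrodeSet":
        df = pd.read_csv(path)
        return cls(
            positions=df[["x", "y", "z"]].to_numpy(),
            labels=df["label"].astype(str).tolist(),
            host_vertex=df["host_vertex"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
        )


# ---------------------------------------------------------------------------
# mesh construction

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
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
    dtype=int,
)


def _subdivide(vertices: np.ndarray, faces: np.ndarray):
    """One loop of midpoint subdivision, re-projecting onto the unit sphere."""
    midpoint_cache: dict = {}
    verts = list(vertices)

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in midpoint_cache:
            m = 0.5 * (verts[i] + verts[j])
            m /= np.linalg.norm(m)
            verts.append(m)
            midpoint_cache[key] = len(verts) - 1
        return midpoint_cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
    return np.array(verts), np.array(new_faces, dtype=int)


def icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere: 12 vertices at level 0, (10*4^k + 2) at level k."""
    v = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    f = _ICO_FACES.copy()
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
    return v, f


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals, normalized to unit length."""
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    n = np.linalg.norm(vn, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return vn / n


def _ellipsoid_mesh(semi_axes, center, target_edge_mm: float) -> TriMesh:
    semi_axes = np.asarray(semi_axes, dtype=float)
    center = np.asarray(center, dtype=float)
    # characteristic unit-sphere edge ~1.0515 at level 0, halves each level
    char_radius = float(np.exp(np.mean(np.log(semi_axes))))
    base_edge = 1.05146 * char_radius
    level = max(0, int(round(np.log2(base_edge / target_edge_mm))))
    v, f = icosphere(level)
    verts = v * semi_axes + center
    # analytic outward ellipsoid normals: grad[(x/a)^2+(y/b)^2+(z/c)^2]
    g = (verts - center) / semi_axes**2
    normals = g / np.linalg.norm(g, axis=1, keepdims=True)
    return TriMesh(vertices=verts, faces=f, vertex_normals=normals)


def make_heart_mesh(semi_axes, center=(0.0, 0.0, 0.0), target_edge_mm: float = 4.0) -> TriMesh:
    """Ellipsoidal stand-in for a fluoroscopy-derived epicardial surface.

    The subdivision level is chosen so the mean edge length lands within
    about 25% of ``target_edge_mm`` (4 mm default, matching typical
    epicardial meshes).
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if np.any(semi_axes <= 0):
        raise InvalidParameterError(f"semi_axes must be positive, got {semi_axes}")
    if target_edge_mm <= 0:
        raise InvalidParameterError("target_edge_mm must be positive")
    mesh = _ellipsoid_mesh(semi_axes, center, target_edge_mm)
    mesh.validate()
    return mesh


def make_torso_tank(heart: TriMesh, scale_factors=(5.0, 5.0, 5.0), target_edge_mm: float = 20.0) -> TriMesh:
    """Ellipsoidal tank strictly enclosing the heart.

    The tank semi-axes are the heart's per-axis extents multiplied by
    ``scale_factors`` (all must exceed 1), centred on the heart centroid.
    """
    scale_factors = np.asarray(scale_factors, dtype=float)
    center = heart.centroid
    extents = np.abs(heart.vertices - center).max(axis=0)
    semi = extents * scale_factors
    if np.any(semi <= 0):
        raise InvalidParameterError("tank semi-axes must be positive")
    tank = _ellipsoid_mesh(semi, center, target_edge_mm)
    # implicit ellipsoid containment test on every heart vertex
    q = ((heart.vertices - center) / semi) ** 2
    inside = q.sum(axis=1) < 1.0
    if not np.all(inside):
        raise ContainmentError(
            f"{int((~inside).sum())} heart vertices lie outside the tank surface"
        )
    tank.validate()
    return tank


def place_electrodes(mesh: TriMesh, n: int, seed: int = 0, prefix: str = "E") -> ElectrodeSet:
    """Farthest-point sampling of ``n`` electrode host vertices.

    Greedy: start from a seeded random vertex, then repeatedly add the
    vertex whose geodesic distance to the already-chosen set is largest.
    Deterministic for a given seed.
    """
    if n > mesh.n_vertices:
        raise InvalidParameterError(f"cannot place {n} electrodes on {mesh.n_vertices} vertices")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    graph = mesh.adjacency()
    start = int(rng.integers(mesh.n_vertices))
    chosen = [start]
    dist_to_set = dijkstra(graph, indices=start)
    for _ in range(n - 1):
        nxt = int(np.argmax(dist_to_set))
        chosen.append(nxt)
        dist_to_set = np.minimum(dist_to_set, dijkstra(graph, indices=nxt))
    chosen = np.array(chosen, dtype=int)
    labels = [f"{prefix}{i:03d}" for i in range(n)]
    return ElectrodeSet(
        positions=mesh.vertices[chosen],
        labels=labels,
        host_vertex=chosen,
        valid=np.ones(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# mesh I/O (ASCII PLY and legacy VTK polydata)


def write_ply(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float nx\nproperty float ny\nproperty float nz\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, nrm in zip(mesh.vertices, mesh.vertex_normals):
            fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g} {nrm[0]:.8g} {nrm[1]:.8g} {nrm[2]:.8g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path) -> TriMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise InvalidParameterError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        has_normals = False
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "property float nx":
                has_normals = True
            elif line == "end_header":
                break
        verts = np.empty((n_vert, 6 if has_normals else 3))
        for i in range(n_vert):
            verts[i] = [float(x) for x in fh.readline().split()]
        faces = np.empty((n_face, 3), dtype=int)
        for i in range(n_face):
            parts = fh.readline().split()
            faces[i] = [int(x) for x in parts[1:4]]
    normals = verts[:, 3:6] if has_normals else None
    return TriMesh(vertices=verts[:, :3], faces=faces, vertex_normals=normals)


def write_vtk(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsurface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_vtk(path) -> TriMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    i = tokens.index("POINTS")
    n_vert = int(tokens[i + 1])
    verts = np.array(tokens[i + 3 : i + 3 + 3 * n_vert], dtype=float).reshape(n_vert, 3)
    j = tokens.index("POLYGONS")
    n_face = int(tokens[j + 1])
    body = np.array(tokens[j + 3 : j + 3 + 4 * n_face], dtype=int).reshape(n_face, 4)
    return TriMesh(vertices=verts, faces=body[:, 1:4])
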