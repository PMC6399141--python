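"""Pinhole-camera projection and the two-stage 3D-to-2D alignment.

Stage 1 minimizes the mean reprojection distance between projected and
manually identified 2D electrode positions; stage 2 refines the camera by
minimizing the mean absolute difference between sock-derived and
optical-derived activation times at paired pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from ecgitank.errors import (
    CostUndefinedError,
    DegenerateCameraError,
    EmptyViewError,
    InvalidParameterError,
    OptimizationFailureError,
)
from ecgitank.geometry import TriMesh

__all__ = [
    "CameraModel",
    "ProjectionResult",
    "Raster",
    "project",
    "rasterize",
    "electrode_cost",
    "optimize_stage1",
    "at_cost",
    "optimize_stage2",
    "visible_submesh",
    "pair_points_to_mask",
]


@dataclass
class CameraModel:
    """Pinhole camera: position, focal centre, roll about the view axis,
    and a focal scale in pixels per unit tangent."""

    x_cop: np.ndarray
    x_foc: np.ndarray
    roll: float = 0.0
    focal_scale: float = None  # type: ignore[assignment]
    image_size: tuple = (100, 100)
    pixel_mm: float = 0.7

    def __post_init__(self):
        self.x_cop = np.asarray(self.x_cop, dtype=float)
        self.x_foc = np.asarray(self.x_foc, dtype=float)
        if np.allclose(self.x_cop, self.x_foc):
            raise DegenerateCameraError("camera position equals focal centre")
        if self.focal_scale is None:
            # one pixel_mm at the focal plane maps to one pixel
            self.focal_scale = float(np.linalg.norm(self.x_foc - self.x_cop) / self.pixel_mm)
        if self.focal_scale <= 0:
            raise InvalidParameterError("focal_scale must be positive")

    def axes(self):
        """Right-handed camera frame (right, up, forward)."""
        fwd = self.x_foc - self.x_cop
        fwd = fwd / np.linalg.norm(fwd)
        world_up = np.array([0.0, 0.0, 1.0])
        if abs(fwd @ world_up) > 0.999:
            world_up = np.array([0.0, 1.0, 0.0])
        up = world_up - (world_up @ fwd) * fwd
        up /= np.linalg.norm(up)
        right = np.cross(fwd, up)
        c, s = np.cos(self.roll), np.sin(self.roll)
        right_r = c * right + s * up
        up_r = -s * right + c * up
        return right_r, up_r, fwd

    @property
    def image_center(self) -> np.ndarray:
        return (np.asarray(self.image_size, dtype=float)[::-1] - 1.0) / 2.0  # (u, v)

    def to_yaml(self, path) -> None:
        data = {
            "x_cop": [float(v) for v in self.x_cop],
            "x_foc": [float(v) for v in self.x_foc],
            "roll": float(self.roll),
            "focal_scale": float(self.focal_scale),
            "image_size": list(self.image_size),
            "pixel_mm": float(self.pixel_mm),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "CameraModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            x_cop=np.array(data["x_cop"]),
            x_foc=np.array(data["x_foc"]),
            roll=data["roll"],
            focal_scale=data["focal_scale"],
            image_size=tuple(data["image_size"]),
            pixel_mm=data["pixel_mm"],
        )


@dataclass
class ProjectionResult:
    """Projected pixel coordinates (u=column, v=row) with depth and visibility."""

    projected_px: np.ndarray
    depth: np.ndarray
    visible: np.ndarray
    reference_px: np.ndarray = None  # type: ignore[assignment]


def project(camera: CameraModel, points: np.ndarray) -> ProjectionResult:
    """Perspective projection of 3D points to image pixels.

    (u, v) = image centre + focal_scale * (x_cam, -y_cam) / z_cam; points at
    or behind the camera plane (z_cam <= 0) and points landing outside the
    image bounds are flagged not visible.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise InvalidParameterError("points must be finite")
    right, up, fwd = camera.axes()
    q = points - camera.x_cop
    x = q @ right
    y = q @ up
    z = q @ fwd
    in_front = z > 1e-12
    zsafe = np.where(in_front, z, 1.0)
    u = camera.image_center[0] + camera.focal_scale * x / zsafe
    v = camera.image_center[1] - camera.focal_scale * y / zsafe
    h, w = camera.image_size
    in_bounds = (u >= -0.5) & (u < w - 0.5) & (v >= -0.5) & (v < h - 0.5)
    visible = in_front & in_bounds
    px = np.stack([u, v], axis=1)
    px[~in_front] = np.nan
    return ProjectionResult(projected_px=px, depth=z, visible=visible)


# ---------------------------------------------------------------------------
# rasterization (shared by the optical renderer and visibility culling)


@dataclass
class Raster:
    """Per-pixel result of z-buffer rasterization."""

    pix_vertex: np.ndarray  # (H, W) visible vertex index, -1 for background
    pix_face: np.ndarray  # (H, W) face index, -1 for background
    pix_depth: np.ndarray  # (H, W) depth along the view axis

    def vertex_map_to_pixels(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.pix_vertex.shape, fill, dtype=float)
        covered = self.pix_vertex >= 0
        out[covered] = np.asarray(values, dtype=float)[self.pix_vertex[covered]]
        return out


def rasterize(camera: CameraModel, mesh: TriMesh) -> Raster:
    """Z-buffer rasterization of front-facing faces onto the image grid.

    Each covered pixel records the depth-nearest face and, as its "visible
    vertex", the face vertex with the largest barycentric weight.
    """
    h, w = camera.image_size
    res = project(camera, mesh.vertices)
    u, v, z = res.projected_px[:, 0], res.projected_px[:, 1], res.depth

    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    face_n = np.cross(
        mesh.vertices[mesh.faces[:, 1]] - mesh.vertices[mesh.faces[:, 0]],
        mesh.vertices[mesh.faces[:, 2]] - mesh.vertices[mesh.faces[:, 0]],
    )
    front = np.einsum("ij,ij->i", face_n, centroids - camera.x_cop) < 0

    depth = np.full((h, w), np.inf)
    pix_vertex = np.full((h, w), -1, dtype=int)
    pix_face = np.full((h, w), -1, dtype=int)

    for fi in np.flatnonzero(front):
        i0, i1, i2 = mesh.faces[fi]
        if not (z[i0] > 0 and z[i1] > 0 and z[i2] > 0):
            continue
        us = np.array([u[i0], u[i1], u[i2]])
        vs = np.array([v[i0], v[i1], v[i2]])
        zs = np.array([z[i0], z[i1], z[i2]])
        c0 = max(0, int(np.ceil(us.min())))
        c1 = min(w - 1, int(np.floor(us.max())))
        r0 = max(0, int(np.ceil(vs.min())))
        r1 = min(h - 1, int(np.floor(vs.max())))
        if c1 < c0 or r1 < r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        det = (vs[1] - vs[2]) * (us[0] - us[2]) + (us[2] - us[1]) * (vs[0] - vs[2])
        if abs(det) < 1e-12:
            continue
        w0 = ((vs[1] - vs[2]) * (cols - us[2]) + (us[2] - us[1]) * (rows - vs[2])) / det
        w1 = ((vs[2] - vs[0]) * (cols - us[2]) + (us[0] - us[2]) * (rows - vs[2])) / det
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        zpix = w0 * zs[0] + w1 * zs[1] + w2 * zs[2]
        rr, cc = rows[inside], cols[inside]
        zz = zpix[inside]
        closer = zz < depth[rr, cc]
        rr, cc, zz = rr[closer], cc[closer], zz[closer]
        if rr.size == 0:
            continue
        depth[rr, cc] = zz
        wstack = np.stack([w0[inside][closer], w1[inside][closer], w2[inside][closer]])
        nearest = np.array([i0, i1, i2])[np.argmax(wstack, axis=0)]
        pix_vertex[rr, cc] = nearest
        pix_face[rr, cc] = fi
    return Raster(pix_vertex=pix_vertex, pix_face=pix_face, pix_depth=depth)


def visible_submesh(camera: CameraModel, heart: TriMesh):
    """Vertices visible in the optical window with their pixel assignment.

    A vertex is kept iff it is front-facing, projects inside the image, and
    is depth-nearest along its pixel ray (checked against the rasterized
    z-buffer).  Returns (vertex_indices, pixel_rc) where pixel_rc[k] is the
    (row, col) pixel of vertex_indices[k].
    """
    res = project(camera, heart.vertices)
    view = heart.vertices - camera.x_cop
    front = np.einsum("ij,ij->i", heart.vertex_normals, view) < 0
    raster = rasterize(camera, heart)
    keep = []
    pixels = []
    tol = 1e-6 * max(1.0, np.abs(res.depth).max())
    for i in np.flatnonzero(front & res.visible):
        c = int(round(res.projected_px[i, 0]))
        r = int(round(res.projected_px[i, 1]))
        if res.depth[i] <= raster.pix_depth[r, c] + max(tol, 0.05 * res.depth[i]):
            keep.append(i)
            pixels.append((r, c))
    if not keep:
        raise EmptyViewError("no heart vertex is visible from the camera")
    return np.array(keep, dtype=int), np.array(pixels, dtype=int)


# ---------------------------------------------------------------------------
# alignment costs


def electrode_cost(camera: CameraModel, e3d: np.ndarray, e2d: np.ndarray) -> float:
    """Mean Euclidean pixel distance between projected and reference electrodes."""
    e3d = np.atleast_2d(e3d)
    e2d = np.atleast_2d(e2d)
    if len(e3d) != len(e2d) or len(e3d) == 0:
        raise InvalidParameterError("correspondence lists must be non-empty and equal length")
    res = project(camera, e3d)
    vis = res.visible
    if not vis.any():
        raise CostUndefinedError("no visible electrode correspondences")
    return float(np.linalg.norm(res.projected_px[vis] - e2d[vis], axis=1).mean())


def pair_points_to_mask(points_px: np.ndarray, mask: np.ndarray, cutoff_px: float | None = None):
    """Nearest in-mask pixel for each (u, v) point; ties break to lowest (row, col).

    Returns (pixel_rc, distance_px) arrays; unpaired points (beyond cutoff)
    get pixel (-1, -1) and distance inf.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise CostUndefinedError("mask is empty")
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    tree = cKDTree(np.stack([cols, rows], axis=1))
    points_px = np.atleast_2d(points_px)
    k = min(4, rows.size)
    dist, idx = tree.query(points_px, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    out_rc = np.full((len(points_px), 2), -1, dtype=int)
    out_d = np.full(len(points_px), np.inf)
    for i in range(len(points_px)):
        ties = np.flatnonzero(dist[i] <= dist[i, 0] + 1e-9)
        j = idx[i, ties].min()  # lexicographically lowest (row, col) by construction
        d = dist[i, 0]
        if cutoff_px is not None and d > cutoff_px:
            continue
        out_rc[i] = (rows[j], cols[j])
        out_d[i] = d
    return out_rc, out_d


def at_cost(
    camera: CameraModel,
    sock_positions: np.ndarray,
    sock_at: np.ndarray,
    optical_at: np.ndarray,
    mask: np.ndarray,
    sock_valid: np.ndarray | None = None,
    optical_valid: np.ndarray | None = None,
) -> float:
    """Mean absolute AT difference between sock electrodes and their nearest
    in-mask optical pixels."""
    sock_positions = np.atleast_2d(sock_positions)
    sock_at = np.asarray(sock_at, dtype=float)
    if sock_valid is None:
        sock_valid = np.isfinite(sock_at)
    if optical_valid is None:
        optical_valid = np.isfinite(optical_at)
    usable_mask = mask & optical_valid
    res = project(camera, sock_positions)
    use = res.visible & sock_valid
    if not use.any():
        raise CostUndefinedError("no visible sock electrode maps into the mask")
    rc, _ = pair_points_to_mask(res.projected_px[use], usable_mask)
    opt = optical_at[rc[:, 0], rc[:, 1]]
    return float(np.abs(sock_at[use] - opt).mean())


# ---------------------------------------------------------------------------
# optimization


def _pack(camera: CameraModel) -> np.ndarray:
    return np.concatenate(
        [camera.x_cop, camera.x_foc, [camera.roll, np.log(camera.focal_scale)]]
    )


def _unpack(p: np.ndarray, template: CameraModel) -> CameraModel:
    return CameraModel(
        x_cop=p[:3],
        x_foc=p[3:6],
        roll=p[6],
        focal_scale=float(np.exp(p[7])),
        image_size=template.image_size,
        pixel_mm=template.pixel_mm,
    )


def optimize_stage1(
    init: CameraModel,
    e3d: np.ndarray,
    e2d: np.ndarray,
    seed: int = 0,
    n_starts: int = 5,
    maxiter: int = 6000,
) -> CameraModel:
    """Derivative-free (Nelder-Mead) fit of the camera to 2D references.

    Runs seeded multi-starts around the initial guess, then polishes the
    best candidate with restarts until the cost stops improving.
    """
    e3d = np.atleast_2d(np.asarray(e3d, dtype=float))
    e2d = np.atleast_2d(np.asarray(e2d, dtype=float))
    if len(e3d) < 4:
        raise InvalidParameterError("at least 4 correspondences required")
    if np.linalg.matrix_rank(e3d - e3d.mean(axis=0), tol=1e-9) < 3:
        raise InvalidParameterError("correspondences must be non-coplanar")

    def cost(p):
        try:
            return electrode_cost(_unpack(p, init), e3d, e2d)
        except (DegenerateCameraError, CostUndefinedError, InvalidParameterError):
            return 1e9

    rng = np.random.default_rng(seed)
    p0 = _pack(init)
    j0 = cost(p0)
    starts = [p0]
    for _ in range(n_starts - 1):
        jitter = np.concatenate([rng.normal(0, 5.0, 6), rng.normal(0, 0.05, 2)])
        starts.append(p0 + jitter)

    best_p, best_j = p0, j0
    opts = {"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3}
    for p in starts:
        r = minimize(cost, p, method="Nelder-Mead", options=opts)
        if r.fun < best_j:
            best_p, best_j = r.x, r.fun
    # polish: restart the simplex from the best vertex until converged
    for _ in range(6):
        r = minimize(
            cost, best_p, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-9},
        )
        if r.fun >= best_j - 1e-12:
            break
        best_p, best_j = r.x, r.fun
    if not np.isfinite(best_j) or best_j > j0 + 1e-12:
        raise OptimizationFailureError("no start reduced the reprojection cost")
    return _unpack(best_p, init)


def optimize_stage2(
    stage1_camera: CameraModel,
    sock_positions: np.ndarray,
    sock_at: np.ndarray,
    optical_at: np.ndarray,
    mask: np.ndarray,
    maxiter: int = 2000,
) -> CameraModel:
    """Refine (X_COP, X_FOC) by minimizing the mean absolute AT difference.

    Bounded within +/-10% of the stage-1 parameter magnitudes; returns the
    stage-1 camera unchanged (with a warning) when the cost landscape is
    flat, e.g. for a uniform AT field.
    """
    cam0 = stage1_camera

    def build(p):
        return CameraModel(
            x_cop=p[:3],
            x_foc=p[3:6],
            roll=cam0.roll,
            focal_scale=cam0.focal_scale,
            image_size=cam0.image_size,
            pixel_mm=cam0.pixel_mm,
        )

    def cost(p):
        try:
            return at_cost(build(p), sock_positions, sock_at, optical_at, mask)
        except (DegenerateCameraError, CostUndefinedError):
            return 1e9

    p0 = np.concatenate([cam0.x_cop, cam0.x_foc])
    j0 = cost(p0)
    span = 0.1 * np.maximum(np.abs(p0), 1.0)
    # flat-cost probe before spending optimizer iterations
    probes = [cost(p0 + d) for d in np.diag(span * 0.5)]
    if max(abs(j - j0) for j in probes) < 1e-12:
        warnings.warn("AT cost is flat; stage-2 refinement skipped", stacklevel=2)
        return cam0

    bounds = list(zip(p0 - span, p0 + span))
    r = minimize(
        cost, p0, method="Nelder-Mead", bounds=bounds,
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
    )
    if r.fun <= j0:
        return build(r.x)
    return cam0
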