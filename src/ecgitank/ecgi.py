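"""Inverse reconstruction of epicardial electrograms from tank potentials.

Method of fundamental solutions over free-space kernels, Tikhonov
regularization solved through the SVD, and CRESO selection of the
regularization parameter (per time sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ecgitank.errors import (
    GeometryError,
    InvalidParameterError,
    ReconstructionRefusedError,
    SingularKernelError,
)
from ecgitank.electro import SignalBlock
from ecgitank.geometry import ElectrodeSet, TriMesh

__all__ = [
    "MFSSources",
    "TikhonovSolution",
    "build_sources",
    "build_system",
    "tikhonov_solve",
    "TikhonovSolver",
    "creso_curve",
    "creso_select",
    "reconstruct_egms",
]


@dataclass
class MFSSources:
    """Fictitious source points: deflated-heart set followed by inflated-tank set."""

    source_points: np.ndarray
    deflate: float
    inflate: float
    n_heart: int

    def __post_init__(self):
        self.source_points = np.asarray(self.source_points, dtype=float)


@dataclass
class TikhonovSolution:
    coeffs: np.ndarray
    lam: float
    residual_norm: float
    solution_norm: float


def _implicit_inside(points: np.ndarray, mesh: TriMesh, margin: float = 0.0) -> np.ndarray:
    """Ellipsoid-implicit containment test about the mesh centroid.

    Generated surfaces are analytic ellipsoids, for which this is exact.
    """
    c = mesh.centroid
    extents = np.abs(mesh.vertices - c).max(axis=0)
    q = ((points - c) / extents) ** 2
    return q.sum(axis=1) < (1.0 - margin)


def build_sources(
    heart: TriMesh,
    tank: TriMesh,
    tank_electrodes: ElectrodeSet | None = None,
    deflate: float = 0.8,
    inflate: float = 1.2,
) -> MFSSources:
    """Scale heart vertices inward and tank electrodes outward about their
    respective centroids to form the fictitious-source cloud."""
    if not (0 < deflate < 1):
        raise InvalidParameterError("deflate must lie strictly in (0, 1)")
    if inflate <= 1:
        raise InvalidParameterError("inflate must exceed 1")
    hc = heart.centroid
    inner = hc + deflate * (heart.vertices - hc)
    tc = tank.centroid
    outer_base = tank_electrodes.positions if tank_electrodes is not None else tank.vertices
    outer = tc + inflate * (outer_base - tc)
    if not np.all(_implicit_inside(inner, heart, margin=1e-9)):
        raise GeometryError("deflated sources are not strictly inside the heart surface")
    if np.any(_implicit_inside(outer, tank, margin=-1e-9)):
        raise GeometryError("inflated sources are not strictly outside the tank surface")
    return MFSSources(
        source_points=np.vstack([inner, outer]),
        deflate=deflate,
        inflate=inflate,
        n_heart=len(inner),
    )


def build_system(
    sources: MFSSources, electrode_positions: np.ndarray, electrode_normals: np.ndarray
) -> np.ndarray:
    """MFS collocation matrix with unknowns [a0, c_1..c_m].

    Dirichlet rows: A[i,0] = 1, A[i,j] = 1/(4*pi*|e_i - s_j|).
    Neumann rows:  A[i,0] = 0, A[i,j] = -((e_i - s_j).n_i)/(4*pi*|e_i - s_j|^3).
    """
    e = np.atleast_2d(electrode_positions)
    n = np.atleast_2d(electrode_normals)
    norms = np.linalg.norm(n, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise InvalidParameterError("electrode normals must be unit length")
    s = sources.source_points
    diff = e[:, None, :] - s[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    if d.min() < 1e-9:
        raise SingularKernelError("an electrode coincides with a source point")
    n_e, m = len(e), len(s)
    A = np.zeros((2 * n_e, m + 1))
    A[:n_e, 0] = 1.0
    A[:n_e, 1:] = 1.0 / (4.0 * np.pi * d)
    A[n_e:, 1:] = -np.einsum("ijk,ik->ij", diff, n) / (4.0 * np.pi * d**3)
    return A


class TikhonovSolver:
    """SVD-backed Tikhonov solver for repeated solves with one matrix."""

    def __init__(self, A: np.ndarray):
        A = np.asarray(A, dtype=float)
        if A.size == 0:
            raise InvalidParameterError("empty system matrix")
        if not np.all(np.isfinite(A)):
            raise InvalidParameterError("non-finite entries in system matrix")
        self.A = A
        self.U, self.s, self.Vt = np.linalg.svd(A, full_matrices=False)

    def solve(self, b: np.ndarray, lam: float) -> TikhonovSolution:
        b = np.asarray(b, dtype=float)
        if not np.all(np.isfinite(b)):
            raise InvalidParameterError("non-finite entries in right-hand side")
        if b.shape[0] != self.A.shape[0]:
            raise InvalidParameterError("right-hand-side length mismatch")
        if lam < 0:
            raise InvalidParameterError("lambda must be non-negative")
        beta = self.U.T @ b
        denom = self.s**2 + lam**2
        xi = self.s * beta / denom
        x = self.Vt.T @ xi
        # closed-form norms from the SVD expansion
        b_perp2 = float(b @ b - beta @ beta)
        resid2 = float(np.sum((lam**2 * beta / denom) ** 2)) + max(b_perp2, 0.0)
        return TikhonovSolution(
            coeffs=x,
            lam=float(lam),
            residual_norm=float(np.sqrt(resid2)),
            solution_norm=float(np.linalg.norm(xi)),
        )

    def solve_many(self, B: np.ndarray, lams: np.ndarray) -> np.ndarray:
        """Columns of B solved with per-column lambdas."""
        beta = self.U.T @ B
        denom = self.s[:, None] ** 2 + np.asarray(lams)[None, :] ** 2
        return self.Vt.T @ (self.s[:, None] * beta / denom)


def tikhonov_solve(A: np.ndarray, b: np.ndarray, lam: float) -> TikhonovSolution:
    """Minimize ||Ax - b||^2 + lam^2 ||x||^2 via the SVD filter factors."""
    return TikhonovSolver(A).solve(b, lam)


def default_lambda_grid(sigma_max: float, n: int = 80) -> np.ndarray:
    return sigma_max * np.logspace(-4, 0, n)


def creso_curve(solver: TikhonovSolver, b: np.ndarray, lam_grid: np.ndarray) -> np.ndarray:
    """Analytic C(lam) = d/dlam [lam^2 ||x_lam||^2] from the SVD.

    C(lam) = sum_i 2 lam s_i^2 beta_i^2 (s_i^2 - lam^2) / (s_i^2 + lam^2)^3.
    """
    beta2 = (solver.U.T @ b) ** 2
    s2 = solver.s**2
    lam = np.asarray(lam_grid)[:, None]
    w = 2.0 * lam * s2[None, :] * (s2[None, :] - lam**2) / (s2[None, :] + lam**2) ** 3
    return w @ beta2


def _first_local_max(C: np.ndarray) -> int | None:
    for i in range(1, len(C) - 1):
        if C[i] > C[i - 1] and C[i] > C[i + 1]:
            return i
    return None


def creso_select(
    A_or_solver, b: np.ndarray, lam_grid: np.ndarray | None = None
) -> float:
    """Smallest grid lambda at which C(lam) has an interior local maximum.

    Falls back (with a warning) to the global maximum when no interior
    local maximum exists, e.g. for b = 0.
    """
    solver = A_or_solver if isinstance(A_or_solver, TikhonovSolver) else TikhonovSolver(A_or_solver)
    if lam_grid is None:
        lam_grid = default_lambda_grid(solver.s.max())
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise InvalidParameterError("empty lambda grid")
    C = creso_curve(solver, np.asarray(b, dtype=float), lam_grid)
    i = _first_local_max(C)
    if i is None:
        warnings.warn("no interior CRESO maximum; falling back to global maximum", stacklevel=2)
        i = int(np.argmax(C))
    return float(lam_grid[i])


def _select_many(solver: TikhonovSolver, B: np.ndarray, lam_grid: np.ndarray) -> np.ndarray:
    """Per-column CRESO selection, vectorized over columns."""
    beta2 = (solver.U.T @ B) ** 2
    s2 = solver.s**2
    lam = lam_grid[:, None]
    W = 2.0 * lam * s2[None, :] * (s2[None, :] - lam**2) / (s2[None, :] + lam**2) ** 3
    C = W @ beta2  # (n_grid, n_cols)
    n_grid = len(lam_grid)
    interior = np.zeros_like(C, dtype=bool)
    if n_grid >= 3:
        interior[1:-1] = (C[1:-1] > C[:-2]) & (C[1:-1] > C[2:])
    idx = np.empty(C.shape[1], dtype=int)
    for j in range(C.shape[1]):
        hits = np.flatnonzero(interior[:, j])
        idx[j] = hits[0] if hits.size else int(np.argmax(C[:, j]))
    return lam_grid[idx]


def reconstruct_egms(
    tank_signals: SignalBlock,
    sources: MFSSources,
    heart: TriMesh,
    electrode_positions: np.ndarray,
    electrode_normals: np.ndarray,
    lam_grid: np.ndarray | None = None,
    wilson_reference: bool = True,
    max_invalid_fraction: float = 0.3,
) -> SignalBlock:
    """Per-sample CRESO + Tikhonov inversion, evaluated at heart nodes.

    Invalid tank channels are excluded by dropping both their Dirichlet and
    Neumann rows.  Valid tank potentials are re-referenced to their mean
    (Wilson-style terminal) before inversion.  The selected lambda trace is
    stored in the output's ``meta['lambda']``.
    """
    valid = tank_signals.valid
    n_all = tank_signals.n_channels
    if (~valid).sum() > max_invalid_fraction * n_all:
        raise ReconstructionRefusedError(
            f"{(~valid).sum()} of {n_all} tank channels invalid; reconstruction refused"
        )
    pos = np.atleast_2d(electrode_positions)[valid]
    nrm = np.atleast_2d(electrode_normals)[valid]
    V = tank_signals.samples[valid]
    if wilson_reference:
        V = V - V.mean(axis=0, keepdims=True)

    A = build_system(sources, pos, nrm)
    solver = TikhonovSolver(A)
    if lam_grid is None:
        lam_grid = default_lambda_grid(solver.s.max())

    B = np.vstack([V, np.zeros_like(V)])
    lams = _select_many(solver, B, np.asarray(lam_grid, dtype=float))
    X = solver.solve_many(B, lams)

    s = sources.source_points
    d = np.linalg.norm(heart.vertices[:, None, :] - s[None, :, :], axis=2)
    E = np.hstack([np.ones((heart.n_vertices, 1)), 1.0 / (4.0 * np.pi * d)])
    out = SignalBlock(
        samples=E @ X,
        rate=tank_signals.rate,
        t0=tank_signals.t0,
        channel_ids=[f"node{i:04d}" for i in range(heart.n_vertices)],
        meta=dict(tank_signals.meta),
    )
    out.meta["lambda"] = lams
    return out
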