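"""Synthetic electrophysiology: activation fields, action potentials,
unipolar electrograms, volume-conductor forward solutions, and the
fluorescence movie.

The synthesis is deliberately simple but constructed so that every marker
convention used downstream holds exactly: the steepest local upstroke of the
transmembrane potential coincides with the steepest negative deflection of
the local unipolar electrogram, and the steepest local repolarization with
the maximum T-wave slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.special import expit, sph_harm_y

from ecgitank.errors import (
    ConfigurationError,
    EmptyViewError,
    IllConditioningError,
    InvalidParameterError,
    OverlapError,
    UnreachableVertexError,
)
from ecgitank.geometry import ElectrodeSet, TriMesh, icosphere

__all__ = [
    "ScenarioConfig",
    "SignalBlock",
    "OpticalStack",
    "TimeMap",
    "simulate_activation",
    "region_around_vertex",
    "synthesize_vm",
    "synthesize_unipolar_egm",
    "sph_transfer_factor",
    "forward_spheres_analytic",
    "real_sph_harm",
    "evaluate_harmonics",
    "forward_mfs",
    "render_optical",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TimeMap:
    """Per-node or per-pixel activation/repolarization times in ms."""

    times: np.ndarray
    valid: np.ndarray
    domain_tag: str = "mesh_nodes"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(~np.isfinite(self.times[self.valid])):
            raise InvalidParameterError("valid entries must carry finite times")

    def valid_times(self) -> np.ndarray:
        return self.times[self.valid]

    def to_csv(self, path) -> None:
        flat_t = self.times.ravel()
        flat_v = self.valid.ravel()
        pd.DataFrame(
            {"id": np.arange(flat_t.size), "time_ms": flat_t, "valid": flat_v.astype(int)}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, shape=None, domain_tag="mesh_nodes") -> "TimeMap":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy()
        v = df["valid"].to_numpy().astype(bool)
        if shape is not None:
            t = t.reshape(shape)
            v = v.reshape(shape)
        return cls(times=t, valid=v, domain_tag=domain_tag)


@dataclass
class SignalBlock:
    """Multichannel time series: ``samples`` is channels x time."""

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    channel_ids: list = None  # type: ignore[assignment]
    valid: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:04d}" for i in range(self.samples.shape[0])]
        if self.valid is None:
            self.valid = np.ones(self.samples.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * 1000.0 / self.rate

    def copy(self) -> "SignalBlock":
        return SignalBlock(
            samples=self.samples.copy(),
            rate=self.rate,
            t0=self.t0,
            channel_ids=list(self.channel_ids),
            valid=self.valid.copy(),
            meta=dict(self.meta),
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.attrs["rate"] = self.rate
            f.attrs["t0"] = self.t0
            f.create_dataset(
                "channel_ids", data=np.array(self.channel_ids, dtype="S32")
            )
            f.create_dataset("valid", data=self.valid)
            for k, v in self.meta.items():
                if np.isscalar(v) or isinstance(v, str):
                    f.attrs[f"meta_{k}"] = v
                else:
                    f.create_dataset(f"meta_{k}", data=np.asarray(v))

    @classmethod
    def from_hdf5(cls, path) -> "SignalBlock":
        with h5py.File(path, "r") as f:
            meta = {}
            for k in f.attrs:
                if k.startswith("meta_"):
                    meta[k[5:]] = f.attrs[k]
            for k in f:
                if k.startswith("meta_"):
                    meta[k[5:]] = f[k][()]
            return cls(
                samples=f["samples"][()],
                rate=float(f.attrs["rate"]),
                t0=float(f.attrs["t0"]),
                channel_ids=[c.decode() for c in f["channel_ids"][()]],
                valid=f["valid"][()].astype(bool),
                meta=meta,
            )


@dataclass
class OpticalStack:
    """Fluorescence movie: ``frames`` is rows x cols x time (100 x 100 x T)."""

    frames: np.ndarray
    rate: float = 1000.0
    pixel_mm: float = 0.7
    mask: np.ndarray = None  # type: ignore[assignment]
    sync: np.ndarray = None  # type: ignore[assignment]
    sync_rate: float = 2000.0
    t0: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.pixel_mm <= 0:
            raise InvalidParameterError("pixel_mm must be positive")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.frames.shape[:2]:
            raise InvalidParameterError("mask shape must match the frame grid")

    @property
    def shape(self):
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) * 1000.0 / self.rate

    def copy(self) -> "OpticalStack":
        return OpticalStack(
            frames=self.frames.copy(),
            rate=self.rate,
            pixel_mm=self.pixel_mm,
            mask=self.mask.copy(),
            sync=None if self.sync is None else self.sync.copy(),
            sync_rate=self.sync_rate,
            t0=self.t0,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames)
            f.create_dataset("mask", data=self.mask)
            if self.sync is not None:
                f.create_dataset("sync", data=self.sync)
            f.attrs["rate"] = self.rate
            f.attrs["pixel_mm"] = self.pixel_mm
            f.attrs["sync_rate"] = self.sync_rate
            f.attrs["t0"] = self.t0

    @classmethod
    def from_hdf5(cls, path) -> "OpticalStack":
        with h5py.File(path, "r") as f:
            return cls(
                frames=f["frames"][()],
                rate=float(f.attrs["rate"]),
                pixel_mm=float(f.attrs["pixel_mm"]),
                mask=f["mask"][()].astype(bool),
                sync=f["sync"][()] if "sync" in f else None,
                sync_rate=float(f.attrs["sync_rate"]),
                t0=float(f.attrs["t0"]),
            )


@dataclass
class ScenarioConfig:
    """One pacing/perfusion sequence of the synthetic study."""

    pacing_site: int
    pacing_cycle_ms: float = 500.0  # 2 Hz pacing
    cv_base: float = 0.5  # mm/ms
    apd_base: float = 200.0
    perfusion_region: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cv_factor_region: float = 1.0
    apd_delta_region: float = 0.0
    noise_snr_db: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.perfusion_region = np.asarray(self.perfusion_region, dtype=int)
        if self.cv_base <= 0:
            raise InvalidParameterError("cv_base must be positive")
        if self.apd_base <= 0:
            raise InvalidParameterError("apd_base must be positive")
        if self.pacing_cycle_ms <= self.apd_base:
            raise InvalidParameterError("pacing cycle must exceed the base APD")

    def apd_field(self, n_vertices: int) -> np.ndarray:
        apd = np.full(n_vertices, self.apd_base)
        if self.perfusion_region.size:
            apd[self.perfusion_region] += self.apd_delta_region
        return apd


# ---------------------------------------------------------------------------
# activation & action potentials


def region_around_vertex(heart: TriMesh, center_vertex: int, radius_mm: float) -> np.ndarray:
    """Vertices within a geodesic radius of a seed vertex (perfusion-bed analogue)."""
    d = dijkstra(heart.adjacency(), indices=int(center_vertex))
    return np.flatnonzero(d <= radius_mm)


def simulate_activation(heart: TriMesh, scenario: ScenarioConfig) -> TimeMap:
    """Ground-truth activation times by shortest-path wavefront propagation.

    Edge travel time is length / cv; edges with both endpoints inside the
    perfusion region use cv_base * cv_factor_region.
    """
    if not 0 <= scenario.pacing_site < heart.n_vertices:
        raise InvalidParameterError(f"pacing_site {scenario.pacing_site} not a mesh vertex")
    graph = heart.adjacency().tocoo()
    in_region = np.zeros(heart.n_vertices, dtype=bool)
    in_region[scenario.perfusion_region] = True
    cv = np.full(len(graph.data), scenario.cv_base)
    slow = in_region[graph.row] & in_region[graph.col]
    cv[slow] *= scenario.cv_factor_region
    travel = graph.copy()
    travel.data = graph.data / cv
    at = dijkstra(travel.tocsr(), indices=scenario.pacing_site)
    if np.any(~np.isfinite(at)):
        raise UnreachableVertexError("mesh is disconnected; some vertices unreachable")
    return TimeMap(times=at, valid=np.ones_like(at, dtype=bool), domain_tag="mesh_nodes")


def synthesize_vm(
    at: TimeMap,
    apd_field: np.ndarray,
    rate: float = 2000.0,
    n_beats: int = 1,
    cycle_ms: float = 500.0,
    tau_up_ms: float = 1.0,
    tau_down_ms: float = 8.0,
) -> SignalBlock:
    """Template action-potential trains on heart nodes, normalized to [0, 1].

    The template is a product of two sigmoids: a fast upstroke centred at AT
    (time constant ~1 ms) and a smooth repolarization centred at AT + APD.
    By construction argmax dVm/dt = AT (+/- 1 sample) and
    argmin dVm/dt = AT + APD (+/- 2 samples).
    """
    if rate < 500:
        raise InvalidParameterError("rate must be at least 500 Hz")
    apd_field = np.asarray(apd_field, dtype=float)
    if np.any(apd_field <= 0):
        raise InvalidParameterError("apd_field must be positive")
    if np.any(apd_field >= cycle_ms):
        raise OverlapError("APD must be shorter than the pacing cycle")
    at_ms = at.times[:, None]
    apd = apd_field[:, None]
    n_samples = int(round(n_beats * cycle_ms * rate / 1000.0))
    t = np.arange(n_samples)[None, :] * 1000.0 / rate
    vm = np.zeros((at_ms.shape[0], n_samples))
    for k in range(n_beats):
        tk = t - k * cycle_ms - at_ms
        vm += expit(tk / tau_up_ms) * expit(-(tk - apd) / tau_down_ms)
    peak = vm.max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    vm /= peak
    return SignalBlock(samples=vm, rate=rate, meta={"cycle_ms": cycle_ms, "n_beats": n_beats})


def synthesize_unipolar_egm(
    vm: SignalBlock,
    heart: TriMesh,
    electrodes: ElectrodeSet,
    rho_mm: float = 8.0,
    gain: float = 1.0,
) -> SignalBlock:
    """Unipolar electrograms as far-field minus local transmembrane activity.

    phi_e(t) = gain * [ sum_j u_j Vm_j(t) - mean_{d<=rho} Vm(t) ], with
    u_j proportional to 1/d^2 over nodes farther than rho, normalized to sum
    to one.  A locally depolarizing region therefore produces the steepest
    negative deflection at its activation time, and a locally repolarizing
    region the steepest positive T-wave slope at its recovery time.
    """
    if vm.n_channels != heart.n_vertices:
        raise InvalidParameterError("vm must be defined on heart vertices")
    d = np.linalg.norm(
        electrodes.positions[:, None, :] - heart.vertices[None, :, :], axis=2
    )
    local = d <= rho_mm
    if np.any(local.sum(axis=1) == 0):
        raise ConfigurationError(f"an electrode has no heart nodes within rho={rho_mm} mm")
    far = ~local
    out = np.zeros((len(electrodes), vm.n_samples))
    for i in range(len(electrodes)):
        v_loc = vm.samples[local[i]].mean(axis=0)
        if far[i].any():
            w = 1.0 / d[i, far[i]] ** 2
            w /= w.sum()
            v_far = w @ vm.samples[far[i]]
        else:
            v_far = v_loc  # degenerate tiny mesh: no far field
        out[i] = gain * (v_far - v_loc)
    return SignalBlock(
        samples=out,
        rate=vm.rate,
        t0=vm.t0,
        channel_ids=list(electrodes.labels),
        valid=electrodes.valid.copy(),
        meta=dict(vm.meta),
    )


# ---------------------------------------------------------------------------
# concentric-spheres analytic volume conductor (oracle)


def sph_transfer_factor(l: int, a: float, R: float, r: float) -> float:
    """Transfer factor per spherical-harmonic degree for the annulus a..R.

    Laplace solution with Dirichlet data on the inner sphere (radius a) and
    zero normal current on the outer sphere (radius R), evaluated at radius
    r in (a, R].
    """
    if not (0 < a < r <= R):
        raise InvalidParameterError(f"need 0 < a < r <= R, got a={a}, r={r}, R={R}")
    if l == 0:
        return 1.0
    c = l / (l + 1.0) * R ** (2 * l + 1)
    return (r**l + c * r ** -(l + 1)) / (a**l + c * a ** -(l + 1))


def forward_spheres_analytic(inner_coeffs: dict, a: float, R: float, eval_radius: float) -> dict:
    """Scale harmonic coefficients from the inner sphere to ``eval_radius``."""
    return {
        (l, m): c * sph_transfer_factor(l, a, R, eval_radius)
        for (l, m), c in inner_coeffs.items()
    }


def real_sph_harm(l: int, m: int, points: np.ndarray, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Real spherical harmonic evaluated on the directions of ``points``."""
    p = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    r = np.linalg.norm(p, axis=1)
    theta = np.arccos(np.clip(p[:, 2] / r, -1, 1))
    phi = np.arctan2(p[:, 1], p[:, 0])
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return y.real
    if m > 0:
        return np.sqrt(2.0) * (-1) ** m * y.real
    return np.sqrt(2.0) * (-1) ** m * y.imag


def evaluate_harmonics(coeffs: dict, points: np.ndarray, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Sum of real spherical harmonics with the given (l, m) coefficients."""
    out = np.zeros(len(points))
    for (l, m), c in coeffs.items():
        out += c * real_sph_harm(l, m, points, center)
    return out


# ---------------------------------------------------------------------------
# forward MFS (deliberately configured differently from the inverse module)


def _kernel(points: np.ndarray, sources: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - sources[None, :, :], axis=2)
    return 1.0 / (4.0 * np.pi * d)


def _kernel_normal(points: np.ndarray, normals: np.ndarray, sources: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - sources[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    return -np.einsum("ijk,ik->ij", diff, normals) / (4.0 * np.pi * d**3)


def _estimate_level(mesh: TriMesh) -> int:
    return max(0, int(round(np.log((mesh.n_vertices - 2) / 10.0) / np.log(4.0))))


def _scaled_cloud(mesh: TriMesh, factor: float, level: int) -> np.ndarray:
    """Ellipsoid-fitted source cloud at a chosen icosphere level."""
    center = mesh.centroid
    extents = np.abs(mesh.vertices - center).max(axis=0)
    v, _ = icosphere(level)
    return v * (extents * factor) + center


def forward_mfs(
    heart_potentials: SignalBlock,
    heart: TriMesh,
    tank: TriMesh,
    tank_electrodes: ElectrodeSet,
    factors: tuple = (0.7, 1.3),
    residual_tol: float = 1e-2,
) -> SignalBlock:
    """Forward problem: heart-surface potentials to tank-electrode potentials.

    Solves the annular Laplace problem (Dirichlet on the heart, zero Neumann
    on the tank) by least-squares collocation on fictitious source clouds,
    then evaluates at the tank electrodes.  Source configuration (deflate
    0.7 / inflate 1.3, vertex-density sources) intentionally differs from the
    inverse module's defaults so inverse tests do not commit an inverse
    crime.
    """
    deflate, inflate = factors
    if not (0 < deflate < 1 < inflate):
        raise InvalidParameterError("factors must satisfy 0 < deflate < 1 < inflate")
    if heart_potentials.n_channels != heart.n_vertices:
        raise InvalidParameterError("heart_potentials must live on heart vertices")
    src_heart = _scaled_cloud(heart, deflate, _estimate_level(heart))
    src_tank = _scaled_cloud(tank, inflate, _estimate_level(tank))
    sources = np.vstack([src_heart, src_tank])

    # dense Neumann collocation on the (analytic-ellipsoid) tank surface so the
    # insulating boundary is well enforced between mesh vertices
    tc = tank.centroid
    extents = np.abs(tank.vertices - tc).max(axis=0)
    vt, _ = icosphere(_estimate_level(tank) + 1)
    neu_pts = vt * extents + tc
    g = (neu_pts - tc) / extents**2
    neu_normals = g / np.linalg.norm(g, axis=1, keepdims=True)

    a_dir = _kernel(heart.vertices, sources)
    a_neu = _kernel_normal(neu_pts, neu_normals, sources)
    n_dir, n_neu = len(a_dir), len(a_neu)
    A = np.zeros((n_dir + n_neu, sources.shape[0] + 1))
    A[:n_dir, 0] = 1.0
    A[:n_dir, 1:] = a_dir
    A[n_dir:, 1:] = a_neu

    B = np.zeros((A.shape[0], heart_potentials.n_samples))
    B[:n_dir] = heart_potentials.samples
    coeffs, *_ = np.linalg.lstsq(A, B, rcond=None)

    resid = np.linalg.norm(A @ coeffs - B)
    scale = max(np.linalg.norm(B), 1e-12)
    rel = resid / scale
    if rel > 10 * residual_tol:
        raise IllConditioningError(f"collocation residual {rel:.3g} above hard tolerance")
    if rel > residual_tol:
        warnings.warn(f"forward collocation residual {rel:.3g} above tolerance", stacklevel=2)

    E = np.hstack([np.ones((len(tank_electrodes), 1)), _kernel(tank_electrodes.positions, sources)])
    return SignalBlock(
        samples=E @ coeffs,
        rate=heart_potentials.rate,
        t0=heart_potentials.t0,
        channel_ids=list(tank_electrodes.labels),
        valid=tank_electrodes.valid.copy(),
        meta=dict(heart_potentials.meta),
    )


# ---------------------------------------------------------------------------
# optical rendering


def render_optical(
    vm: SignalBlock,
    heart: TriMesh,
    camera,
    scenario: ScenarioConfig | None = None,
    *,
    blur_sigma_px: float = 1.0,
    noise_snr_db: float | None = None,
    opt_rate: float = 1000.0,
    exposure_start_ms: float = 0.0,
    seed: int | None = None,
) -> OpticalStack:
    """Z-buffer render of the heart's fluorescence as seen by ``camera``.

    Each covered pixel takes the normalized Vm of its visible vertex
    (nearest-vertex shading, so per-pixel markers match that vertex exactly
    before blurring), scaled by a Lambertian amplitude factor.  In-plane
    Gaussian blur stands in for photon scattering; seeded Gaussian noise is
    added everywhere including the background.  The sync channel is a square
    wave at the electrical rate, high exactly during exposure.
    """
    from scipy.ndimage import gaussian_filter

    from ecgitank.camera import rasterize

    if scenario is not None:
        if noise_snr_db is None:
            noise_snr_db = scenario.noise_snr_db
        if seed is None:
            seed = scenario.seed
    rng = np.random.default_rng(seed)

    raster = rasterize(camera, heart)
    covered = raster.pix_vertex >= 0
    if not covered.any():
        raise EmptyViewError("heart lies entirely outside the camera frustum")
    h, w = covered.shape

    step = vm.rate / opt_rate
    if abs(step - round(step)) > 1e-9:
        raise InvalidParameterError("electrical rate must be an integer multiple of opt_rate")
    step = int(round(step))
    start = int(round(exposure_start_ms * vm.rate / 1000.0))
    tidx = np.arange(start, vm.n_samples, step)
    n_t = len(tidx)
    if n_t == 0:
        raise InvalidParameterError("exposure window lies outside the simulated signals")

    view = (heart.vertices - camera.x_cop)
    view /= np.linalg.norm(view, axis=1, keepdims=True)
    lambert = np.clip(-np.einsum("ij,ij->i", heart.vertex_normals, view), 0.0, 1.0)

    frames = np.zeros((h, w, n_t))
    vidx = raster.pix_vertex[covered]
    frames[covered] = lambert[vidx, None] * vm.samples[np.ix_(vidx, tidx)]

    if blur_sigma_px > 0:
        frames = gaussian_filter(frames, sigma=(blur_sigma_px, blur_sigma_px, 0))

    if noise_snr_db is not None and np.isfinite(noise_snr_db):
        sigma = frames.max() * 10 ** (-noise_snr_db / 20.0)
        frames = frames + rng.normal(0.0, sigma, size=frames.shape)

    sync = np.zeros(vm.n_samples)
    t_elec = vm.times_ms - vm.t0
    exposure_end = exposure_start_ms + n_t * 1000.0 / opt_rate
    sync[(t_elec >= exposure_start_ms) & (t_elec < exposure_end)] = 1.0

    # the optical clock starts at frame 0; sync_align shifts the electrical
    # t0 so the two timebases agree
    return OpticalStack(
        frames=frames,
        rate=opt_rate,
        pixel_mm=camera.pixel_mm,
        mask=covered,
        sync=sync,
        sync_rate=vm.rate,
        t0=0.0,
    )
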