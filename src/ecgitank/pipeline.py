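"""End-to-end study analogue driven by one YAML config.

simulate -> preprocess -> align -> reconstruct -> markers -> compare, one
run directory per invocation, deterministic for a given seed.  Each stage
reads the artifacts of earlier stages from the run directory, so the CLI
can execute stages individually.
"""

from __future__ import annotations

import copy
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ecgitank import __version__
from ecgitank.camera import (
    CameraModel,
    optimize_stage1,
    optimize_stage2,
    project,
    rasterize,
    visible_submesh,
)
from ecgitank.ecgi import build_sources, reconstruct_egms
from ecgitank.electro import (
    OpticalStack,
    ScenarioConfig,
    SignalBlock,
    TimeMap,
    forward_mfs,
    region_around_vertex,
    render_optical,
    simulate_activation,
    synthesize_unipolar_egm,
    synthesize_vm,
)
from ecgitank.errors import StageError
from ecgitank.geometry import (
    ElectrodeSet,
    make_heart_mesh,
    make_torso_tank,
    place_electrodes,
    read_ply,
    write_ply,
)
from ecgitank.markers import (
    at_map_from_egms,
    at_map_from_optical,
    global_activation_field,
    rt_map_from_egms,
    rt_map_from_optical,
)
from ecgitank.metrics import compare_maps, gradient_profile, pair_to_pixels
from ecgitank.sigproc import (
    DataMask,
    compute_mask,
    drop_bad_channels,
    spatial_average,
    sync_align,
    temporal_average,
)

STAGES = ["simulate", "preprocess", "align", "reconstruct", "markers", "compare"]

DEFAULT_CONFIG = {
    "seed": 1,
    "geometry": {
        "heart_semi_axes": [30.0, 30.0, 30.0],
        "heart_center": [0.0, 0.0, 0.0],
        "heart_edge_mm": 7.0,
        "tank_scale": [1.3, 1.3, 1.3],
        "tank_edge_mm": 9.0,
        "n_sock": 64,
        "n_tank": 128,
    },
    "camera": {
        "direction": [0.0, -1.0, 0.0],
        "distance_mm": 220.0,
        "init_perturb_mm": 10.0,
        "ref_jitter_px": 0.5,
    },
    "signals": {
        "elec_rate": 2000.0,
        "opt_rate": 1000.0,
        "egm_rho_mm": 8.0,
        "tank_noise_snr_db": 40.0,
        "optical_noise_snr_db": 25.0,
        "optical_blur_px": 1.0,
        "exposure_start_ms": 10.0,
    },
    "scenario_defaults": {
        "pacing_cycle_ms": 500.0,
        "cv_base": 0.5,
        "apd_base": 200.0,
        "region_radius_mm": 15.0,
    },
    "sequences": [],
    "mfs": {"deflate": 0.8, "inflate": 1.2, "forward_factors": [0.7, 1.3]},
    "markers": {
        "rt_window": [50.0, 450.0],
        "gaf_max_lag_ms": 30.0,
        "gaf_cc_min": 0.5,
        "gaf_mu": 0.01,
    },
    "metrics": {"pairing_cutoff_px": 5.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path, seed_override: int | None = None) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    if seed_override is not None:
        cfg["seed"] = int(seed_override)
    if not cfg["sequences"]:
        raise StageError("config", "at least one sequence must be configured")
    return cfg


def _nearest_vertex(mesh, point) -> int:
    return int(np.argmin(np.linalg.norm(mesh.vertices - np.asarray(point, float), axis=1)))


def _seq_dirs(run_dir: Path, cfg: dict):
    return [run_dir / f"seq_{i:03d}" for i in range(len(cfg["sequences"]))]


def _require(path: Path, stage: str):
    if not path.exists():
        raise StageError(stage, f"missing input artifact {path}; run earlier stages first")
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict, run_dir: Path) -> None:
    g = cfg["geometry"]
    s = cfg["signals"]
    sd = cfg["scenario_defaults"]
    seed = int(cfg["seed"])
    geo_dir = run_dir / "geometry"
    geo_dir.mkdir(parents=True, exist_ok=True)

    heart = make_heart_mesh(g["heart_semi_axes"], g["heart_center"], g["heart_edge_mm"])
    tank = make_torso_tank(heart, g["tank_scale"], g["tank_edge_mm"])
    sock = place_electrodes(heart, g["n_sock"], seed=seed, prefix="S")
    telec = place_electrodes(tank, g["n_tank"], seed=seed + 1, prefix="T")
    write_ply(heart, geo_dir / "heart.ply")
    write_ply(tank, geo_dir / "tank.ply")
    sock.to_csv(geo_dir / "sock.csv")
    telec.to_csv(geo_dir / "tank_electrodes.csv")

    cam_cfg = cfg["camera"]
    direction = np.asarray(cam_cfg["direction"], float)
    direction = direction / np.linalg.norm(direction)
    center = np.asarray(g["heart_center"], float)
    truth_cam = CameraModel(
        x_cop=center + direction * cam_cfg["distance_mm"], x_foc=center
    )
    truth_cam.to_yaml(geo_dir / "camera_truth.yaml")

    # every-vertex electrode set: epicardial surface electrograms, of which
    # the sock channels are a subset
    allvert = ElectrodeSet(
        positions=heart.vertices,
        labels=[f"v{i:04d}" for i in range(heart.n_vertices)],
        host_vertex=np.arange(heart.n_vertices),
        valid=np.ones(heart.n_vertices, dtype=bool),
    )

    for i, (seq, sdir) in enumerate(zip(cfg["sequences"], _seq_dirs(run_dir, cfg))):
        sdir.mkdir(parents=True, exist_ok=True)
        try:
            pacing = (
                int(seq["pacing_vertex"])
                if "pacing_vertex" in seq
                else _nearest_vertex(heart, seq["pacing_point"])
            )
            region = np.array([], dtype=int)
            if "region_center_point" in seq or "region_center_vertex" in seq:
                cvert = (
                    int(seq["region_center_vertex"])
                    if "region_center_vertex" in seq
                    else _nearest_vertex(heart, seq["region_center_point"])
                )
                region = region_around_vertex(
                    heart, cvert, seq.get("region_radius_mm", sd["region_radius_mm"])
                )
            scen = ScenarioConfig(
                pacing_site=pacing,
                pacing_cycle_ms=seq.get("pacing_cycle_ms", sd["pacing_cycle_ms"]),
                cv_base=seq.get("cv_base", sd["cv_base"]),
                apd_base=seq.get("apd_base", sd["apd_base"]),
                perfusion_region=region,
                cv_factor_region=seq.get("cv_factor_region", 1.0),
                apd_delta_region=seq.get("apd_delta_region", 0.0),
                noise_snr_db=s["optical_noise_snr_db"],
                seed=seed + 10 * i,
            )
            at = simulate_activation(heart, scen)
            at.to_csv(sdir / "at_truth.csv")
            apd = scen.apd_field(heart.n_vertices)
            np.savetxt(sdir / "apd_field.csv", apd, delimiter=",")

            vm = synthesize_vm(
                at, apd, rate=s["elec_rate"], n_beats=1, cycle_ms=scen.pacing_cycle_ms
            )
            heart_phi = synthesize_unipolar_egm(vm, heart, allvert, rho_mm=s["egm_rho_mm"])
            heart_phi.to_hdf5(sdir / "heart_phi.h5")
            sock_egms = SignalBlock(
                samples=heart_phi.samples[sock.host_vertex],
                rate=heart_phi.rate,
                channel_ids=list(sock.labels),
                valid=sock.valid.copy(),
                meta=dict(heart_phi.meta),
            )
            sock_egms.to_hdf5(sdir / "sock_egms.h5")

            tank_sig = forward_mfs(
                heart_phi, heart, tank, telec, factors=tuple(cfg["mfs"]["forward_factors"])
            )
            rng = np.random.default_rng(seed + 10 * i + 5)
            if s["tank_noise_snr_db"] is not None:
                sigma = np.linalg.norm(tank_sig.samples) / np.sqrt(
                    tank_sig.samples.size
                ) * 10 ** (-s["tank_noise_snr_db"] / 20.0)
                tank_sig.samples = tank_sig.samples + rng.normal(
                    0, sigma, tank_sig.samples.shape
                )
            tank_sig.to_hdf5(sdir / "tank_potentials.h5")

            stack = render_optical(
                vm,
                heart,
                truth_cam,
                scen,
                blur_sigma_px=s["optical_blur_px"],
                noise_snr_db=s["optical_noise_snr_db"],
                opt_rate=s["opt_rate"],
                exposure_start_ms=s["exposure_start_ms"],
                seed=seed + 10 * i + 7,
            )
            stack.to_hdf5(sdir / "optical_raw.h5")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-tagged abort
            raise StageError("simulate", f"sequence {i}: {exc}") from exc


def stage_preprocess(cfg: dict, run_dir: Path) -> None:
    for i, sdir in enumerate(_seq_dirs(run_dir, cfg)):
        try:
            stack = OpticalStack.from_hdf5(_require(sdir / "optical_raw.h5", "preprocess"))
            stack = temporal_average(stack)
            mask = compute_mask(stack)
            stack.mask = mask.grid
            stack = spatial_average(stack)
            mask.to_csv(sdir / "mask.csv")
            stack.to_hdf5(sdir / "optical_filtered.h5")

            for name in ("sock_egms", "tank_potentials"):
                sig = SignalBlock.from_hdf5(_require(sdir / f"{name}.h5", "preprocess"))
                sig = drop_bad_channels(sig)
                sig = temporal_average(sig)
                if stack.sync is not None:
                    _, sig = sync_align(sig, stack.sync, stack.sync_rate)
                sig.to_hdf5(sdir / f"{name}_clean.h5")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("preprocess", f"sequence {i}: {exc}") from exc


def stage_align(cfg: dict, run_dir: Path) -> None:
    geo_dir = run_dir / "geometry"
    seed = int(cfg["seed"])
    try:
        sock = ElectrodeSet.from_csv(_require(geo_dir / "sock.csv", "align"))
        truth_cam = CameraModel.from_yaml(_require(geo_dir / "camera_truth.yaml", "align"))
        cam_cfg = cfg["camera"]
        rng = np.random.default_rng(seed + 1000)

        ref = project(truth_cam, sock.positions)
        e2d = ref.projected_px + rng.normal(0, cam_cfg["ref_jitter_px"], (len(sock), 2))

        d_cop = rng.normal(0, 1, 3)
        d_foc = rng.normal(0, 1, 3)
        perturb = cam_cfg["init_perturb_mm"]
        init = CameraModel(
            x_cop=truth_cam.x_cop + perturb * d_cop / np.linalg.norm(d_cop),
            x_foc=truth_cam.x_foc + 0.3 * perturb * d_foc / np.linalg.norm(d_foc),
            roll=truth_cam.roll,
            focal_scale=truth_cam.focal_scale,
            image_size=truth_cam.image_size,
            pixel_mm=truth_cam.pixel_mm,
        )
        vis = ref.visible
        cam1 = optimize_stage1(init, sock.positions[vis], e2d[vis], seed=seed)

        # stage 2 uses the first sequence's activation maps
        sdir = _seq_dirs(run_dir, cfg)[0]
        sock_egms = SignalBlock.from_hdf5(_require(sdir / "sock_egms_clean.h5", "align"))
        stack = OpticalStack.from_hdf5(_require(sdir / "optical_filtered.h5", "align"))
        mask = DataMask.from_csv(_require(sdir / "mask.csv", "align"))
        sock_at = at_map_from_egms(sock_egms)
        opt_at = at_map_from_optical(stack, mask.grid)
        # posterior (occluded) electrodes are excluded from the AT cost
        heart = read_ply(_require(geo_dir / "heart.ply", "align"))
        vis_idx, _ = visible_submesh(cam1, heart)
        front = np.isin(sock.host_vertex, vis_idx)
        cam2 = optimize_stage2(
            cam1,
            sock.positions[front],
            sock_at.times[front],
            opt_at.times,
            mask.grid & opt_at.valid,
        )
        cam1.to_yaml(run_dir / "camera_stage1.yaml")
        cam2.to_yaml(run_dir / "camera_fitted.yaml")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("align", str(exc)) from exc


def stage_reconstruct(cfg: dict, run_dir: Path) -> None:
    geo_dir = run_dir / "geometry"
    try:
        heart = read_ply(_require(geo_dir / "heart.ply", "reconstruct"))
        tank = read_ply(_require(geo_dir / "tank.ply", "reconstruct"))
        telec = ElectrodeSet.from_csv(_require(geo_dir / "tank_electrodes.csv", "reconstruct"))
        m = cfg["mfs"]
        sources = build_sources(heart, tank, telec, m["deflate"], m["inflate"])
        normals = tank.vertex_normals[telec.host_vertex]
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("reconstruct", str(exc)) from exc
    for i, sdir in enumerate(_seq_dirs(run_dir, cfg)):
        try:
            tank_sig = SignalBlock.from_hdf5(
                _require(sdir / "tank_potentials_clean.h5", "reconstruct")
            )
            rec = reconstruct_egms(tank_sig, sources, heart, telec.positions, normals)
            lam = rec.meta.pop("lambda")
            pd.DataFrame({"sample": np.arange(len(lam)), "lambda": lam}).to_csv(
                sdir / "lambda_trace.csv", index=False
            )
            rec.to_hdf5(sdir / "ecgi_egms.h5")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("reconstruct", f"sequence {i}: {exc}") from exc


def stage_markers(cfg: dict, run_dir: Path) -> None:
    geo_dir = run_dir / "geometry"
    heart = read_ply(_require(geo_dir / "heart.ply", "markers"))
    rt_win = tuple(cfg["markers"]["rt_window"])
    mk = cfg["markers"]
    for i, sdir in enumerate(_seq_dirs(run_dir, cfg)):
        try:
            sock_egms = SignalBlock.from_hdf5(_require(sdir / "sock_egms_clean.h5", "markers"))
            sock_at = at_map_from_egms(sock_egms)
            sock_rt = rt_map_from_egms(sock_egms, sock_at, rt_win)
            sock_at.to_csv(sdir / "sock_at.csv")
            sock_rt.to_csv(sdir / "sock_rt.csv")

            stack = OpticalStack.from_hdf5(_require(sdir / "optical_filtered.h5", "markers"))
            mask = DataMask.from_csv(_require(sdir / "mask.csv", "markers"))
            opt_at = at_map_from_optical(stack, mask.grid)
            opt_rt = rt_map_from_optical(stack, opt_at, rt_win)
            opt_at.to_csv(sdir / "optical_at.csv")
            opt_rt.to_csv(sdir / "optical_rt.csv")

            rec = SignalBlock.from_hdf5(_require(sdir / "ecgi_egms.h5", "markers"))
            ecgi_at = global_activation_field(
                rec,
                heart.edges(),
                max_lag_ms=mk["gaf_max_lag_ms"],
                cc_min=mk["gaf_cc_min"],
                mu=mk["gaf_mu"],
            )
            ecgi_rt = rt_map_from_egms(rec, ecgi_at, rt_win)
            ecgi_at.to_csv(sdir / "ecgi_at.csv")
            ecgi_rt.to_csv(sdir / "ecgi_rt.csv")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("markers", f"sequence {i}: {exc}") from exc


def stage_compare(cfg: dict, run_dir: Path) -> None:
    geo_dir = run_dir / "geometry"
    try:
        heart = read_ply(_require(geo_dir / "heart.ply", "compare"))
        sock = ElectrodeSet.from_csv(_require(geo_dir / "sock.csv", "compare"))
        cam = CameraModel.from_yaml(_require(run_dir / "camera_fitted.yaml", "compare"))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("compare", str(exc)) from exc
    cutoff = cfg["metrics"]["pairing_cutoff_px"]
    rows = []
    for i, sdir in enumerate(_seq_dirs(run_dir, cfg)):
        try:
            mask = DataMask.from_csv(_require(sdir / "mask.csv", "compare"))
            grid_shape = mask.grid.shape
            opt_at = TimeMap.from_csv(sdir / "optical_at.csv", grid_shape, "optical_pixels")
            opt_rt = TimeMap.from_csv(sdir / "optical_rt.csv", grid_shape, "optical_pixels")
            sock_at = TimeMap.from_csv(sdir / "sock_at.csv", domain_tag="sock_electrodes")
            sock_rt = TimeMap.from_csv(sdir / "sock_rt.csv", domain_tag="sock_electrodes")
            ecgi_at = TimeMap.from_csv(sdir / "ecgi_at.csv", domain_tag="ecgi_nodes")
            ecgi_rt = TimeMap.from_csv(sdir / "ecgi_rt.csv", domain_tag="ecgi_nodes")

            vis_idx, _ = visible_submesh(cam, heart)
            sock_front = np.isin(sock.host_vertex, vis_idx)
            res = project(cam, sock.positions)
            for tag, src_map, pix_map in [
                ("sock_vs_optical_at", sock_at, opt_at),
                ("sock_vs_optical_rt", sock_rt, opt_rt),
            ]:
                usable = mask.grid & pix_map.valid
                pairs = pair_to_pixels(
                    res.projected_px, usable, res.visible & sock_front & src_map.valid, cutoff
                )
                cmp_res = compare_maps(src_map.times, pix_map.times, pairs)
                rows.append((f"seq_{i:03d}", tag, cmp_res.cc, cmp_res.rmse, cmp_res.n_pairs))

            vres = project(cam, heart.vertices[vis_idx])
            for tag, node_map, pix_map in [
                ("ecgi_vs_optical_at", ecgi_at, opt_at),
                ("ecgi_vs_optical_rt", ecgi_rt, opt_rt),
            ]:
                usable = mask.grid & pix_map.valid
                node_valid = node_map.valid[vis_idx]
                pairs = pair_to_pixels(
                    vres.projected_px, usable, vres.visible & node_valid, cutoff
                )
                node_vals = node_map.times[vis_idx]
                cmp_res = compare_maps(node_vals, pix_map.times, pairs)
                rows.append((f"seq_{i:03d}", tag, cmp_res.cc, cmp_res.rmse, cmp_res.n_pairs))

            _write_gradient_profiles(cfg, i, sdir, heart, cam, mask, opt_rt, ecgi_rt)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("compare", f"sequence {i}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["sequence", "comparison", "cc", "rmse", "n_pairs"])
    df.to_csv(run_dir / "summary.csv", index=False, float_format="%.6f")


def _write_gradient_profiles(cfg, i, sdir, heart, cam, mask, opt_rt, ecgi_rt) -> None:
    """RT-vs-distance profiles across the perfusion-region border (when present)."""
    seq = cfg["sequences"][i]
    if "region_center_point" not in seq and "region_center_vertex" not in seq:
        return
    cvert = (
        int(seq["region_center_vertex"])
        if "region_center_vertex" in seq
        else _nearest_vertex(heart, seq["region_center_point"])
    )
    rad = seq.get("region_radius_mm", cfg["scenario_defaults"]["region_radius_mm"])
    region = region_around_vertex(heart, cvert, 2.0 * rad)  # box spans the border
    res = project(cam, heart.vertices[region])
    if not res.visible.any():
        return
    px = res.projected_px[res.visible]
    r0, r1 = int(px[:, 1].min()), int(px[:, 1].max()) + 1
    c0, c1 = int(px[:, 0].min()), int(px[:, 0].max()) + 1
    ref_res = project(cam, heart.vertices[[cvert]])
    ref = (int(round(ref_res.projected_px[0, 1])), int(round(ref_res.projected_px[0, 0])))
    try:
        prof_opt = gradient_profile(
            opt_rt.times, opt_rt.valid & mask.grid, (r0, r1, c0, c1), ref, cam.pixel_mm, "optical"
        )
    except Exception:  # noqa: BLE001 - profile is auxiliary output
        return
    raster = rasterize(cam, heart)
    ecgi_px = raster.vertex_map_to_pixels(ecgi_rt.times)
    prof_ecgi = gradient_profile(
        ecgi_px, np.isfinite(ecgi_px), (r0, r1, c0, c1), ref, cam.pixel_mm, "ecgi"
    )
    pd.concat([prof_opt.samples, prof_ecgi.samples], ignore_index=True).to_csv(
        sdir / "rt_gradient_profile.csv", index=False
    )


def run_pipeline(config_path, run_dir, seed: int | None = None, stages=None) -> Path:
    """Execute the requested stages (default: all) into ``run_dir``."""
    cfg = load_config(config_path, seed)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(cfg["seed"]),
        "version": __version__,
        "config": cfg,
    }
    with open(run_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    shutil.copy(config_path, run_dir / "config.yaml")
    stage_fns = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "align": stage_align,
        "reconstruct": stage_reconstruct,
        "markers": stage_markers,
        "compare": stage_compare,
    }
    for name in stages or STAGES:
        stage_fns[name](cfg, run_dir)
    return run_dir
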