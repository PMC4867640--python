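"""End-to-end orchestration: simulate -> georeference -> select -> analyse.

A single YAML-serialisable :class:`RunConfig` drives the whole pipeline:
synthetic bathymetry and surveys (or pose/observation CSV inputs),
footprint georeferencing and image selection, bootstrap density tables,
contour-distance KS tests, broad-scale neighbour-K dispersion, fine-scale
quadrat VMR tests, and camera community comparisons.  Every output is
stamped with the config hash and seed; reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import density as dens
from . import pattern as patt
from . import terrain as terr
from .geometry import (
    CameraModel,
    FootprintSet,
    calibrate_fov,
    project_footprints,
    select_images,
)
from .reference import OBLIQUE_FOOTPRINT_M2, TARGET_ALTITUDE_M, VERTICAL_FOOTPRINT_M2
from .synthetic import (
    BathymetryGrid,
    PointPatternSpec,
    SurveyDesign,
    detect_fish,
    gen_bathymetry,
    gen_point_pattern,
    gen_track_and_poses,
)

__all__ = ["RunConfig", "run", "default_cameras", "PATTERN_EDGE_PAD_M"]

#: Margin (m) by which generated fish patterns extend beyond the survey
#: domain, so boundary footprints sample fully populated seafloor.
PATTERN_EDGE_PAD_M = 50.0


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    # --- real-data paths (alternative to the simulate block) ---
    pose_csv: str | None = None  # one row per photograph (pose at capture)
    observations_csv: str | None = None  # image_id, taxon, easting, northing
    bathymetry_grid: str | None = None  # ESRI ASCII grid
    data_camera: str = "vertical"
    # --- simulate block ---
    plain_depth: float = 4850.0
    hill_height: float = 240.0
    hill_sigma: float = 850.0
    cell_size: float = 20.0
    domain: tuple[float, float] = (10_000.0, 10_000.0)
    regime: str = "csr"
    intensity: float = 700.0
    thomas_sigma: float = 50.0
    thomas_mean_offspring: float = 20.0
    hardcore_radius: float = 20.0
    broad: bool = True
    broad_extent: tuple[float, float] = (10_000.0, 10_000.0)
    broad_spacing: float = 1_000.0
    fine_origins: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "F1": (4_500.0, 8_200.0),
            "F2": (4_500.0, 5_900.0),
            "F3": (500.0, 500.0),
        }
    )
    fine_extent: tuple[float, float] = (1_000.0, 1_000.0)
    fine_spacing: float = 90.0
    photo_interval: float = 0.87
    speed: float = 1.2
    # --- analysis toggles and sizes ---
    do_density: bool = True
    do_terrain: bool = True
    do_pattern: bool = True
    do_community: bool = True
    n_boot: int = 10_000
    n_ks_boot: int = 1_000
    n_sim: int = 1_000
    n_mc: int = 10_000
    n_community_groups: int = 4
    ks_empty_subsample: int = 3_000
    taxa_of_interest: tuple[str, ...] = (
        "Coryphaenoides profundicolus",
        "Coryphaenoides sp. 1",
    )

    @property
    def data_mode(self) -> bool:
        return self.pose_csv is not None

    def validate(self) -> None:
        errors = []
        if self.data_mode:
            if self.observations_csv is None:
                errors.append("observations_csv: required with pose_csv")
            if self.bathymetry_grid is None:
                errors.append("bathymetry_grid: required with pose_csv")
            if self.data_camera not in ("vertical", "oblique"):
                errors.append(f"data_camera: unknown value {self.data_camera!r}")
        if self.cell_size <= 0:
            errors.append("cell_size: must be > 0")
        if self.intensity < 0:
            errors.append("intensity: must be >= 0")
        if self.regime not in ("csr", "thomas", "hardcore", "covariate"):
            errors.append(f"regime: unknown value {self.regime!r}")
        for name, origin in self.fine_origins.items():
            if (
                origin[0] < 0
                or origin[1] < 0
                or origin[0] + self.fine_extent[0] > self.domain[0]
                or origin[1] + self.fine_extent[1] > self.domain[1]
            ):
                errors.append(f"fine_origins.{name}: survey exits the domain")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("domain", "broad_extent", "fine_extent"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "fine_origins" in raw:
            raw["fine_origins"] = {k: tuple(v) for k, v in raw["fine_origins"].items()}
        if "taxa_of_interest" in raw:
            raw["taxa_of_interest"] = tuple(raw["taxa_of_interest"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["domain"] = list(self.domain)
        d["broad_extent"] = list(self.broad_extent)
        d["fine_extent"] = list(self.fine_extent)
        d["fine_origins"] = {k: list(v) for k, v in self.fine_origins.items()}
        d["taxa_of_interest"] = list(self.taxa_of_interest)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def default_cameras() -> dict[str, CameraModel]:
    """Vertical and oblique cameras calibrated to the printed footprint areas."""
    return {
        "vertical": calibrate_fov("vertical", VERTICAL_FOOTPRINT_M2, TARGET_ALTITUDE_M),
        "oblique": calibrate_fov("oblique", OBLIQUE_FOOTPRINT_M2, TARGET_ALTITUDE_M),
    }


def _simulate_surveys(cfg: RunConfig, bathy: BathymetryGrid):
    designs = []
    if cfg.broad:
        designs.append(
            SurveyDesign(
                scale="broad",
                extent=cfg.broad_extent,
                line_spacing=cfg.broad_spacing,
                photo_interval=cfg.photo_interval,
                speed=cfg.speed,
                origin=(0.0, 0.0),
                survey_id="B1",
            )
        )
    for name, origin in sorted(cfg.fine_origins.items()):
        designs.append(
            SurveyDesign(
                scale="fine",
                extent=cfg.fine_extent,
                line_spacing=cfg.fine_spacing,
                photo_interval=cfg.photo_interval,
                speed=cfg.speed,
                crosshatch=True,
                origin=origin,
                survey_id=name,
            )
        )
    cams = default_cameras()
    surveys = {}
    id_offset = 0
    for i, design in enumerate(designs):
        track = gen_track_and_poses(design, bathy, seed=cfg.seed + 1000 + i)
        per_cam = {}
        for cam_name, cam in cams.items():
            fps = select_images(track.footprints(cam))
            fps.image_id = fps.image_id + id_offset
            id_offset += len(fps) + 1
            per_cam[cam_name] = fps
        surveys[design.survey_id] = {"design": design, "track": track, **per_cam}
    return surveys


def _load_data_inputs(config: RunConfig):
    """Georeference real pose/observation/bathymetry files.

    The pose CSV carries one row per photograph (pose at capture); the
    whole file is treated as one transect survey "D1".  Observations
    whose image no longer exists after selection (altitude filter,
    oblique decimation) are dropped.
    """
    from .io import read_ascii_grid, read_pose_csv

    bathy = read_ascii_grid(config.bathymetry_grid)
    poses = read_pose_csv(config.pose_csv)
    cam = default_cameras()[config.data_camera]
    fps = project_footprints(
        poses["easting"].to_numpy(),
        poses["northing"].to_numpy(),
        poses["altitude"].to_numpy(),
        poses["heading"].to_numpy(),
        poses["pitch"].to_numpy(),
        poses["roll"].to_numpy(),
        cam,
        timestamp=poses["timestamp"].to_numpy(),
        survey_id="D1",
    )
    fps = select_images(fps)
    obs = pd.read_csv(config.observations_csv)
    required = {"image_id", "taxon", "easting", "northing"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations_csv missing columns: {sorted(missing)}")
    obs = obs[obs["image_id"].isin(fps.image_id)].copy()
    obs["camera"] = config.data_camera
    obs["survey_id"] = "D1"
    surveys = {"D1": {"design": None, config.data_camera: fps}}
    return bathy, surveys, {config.data_camera: obs}, {config.data_camera: fps}


def run(config: RunConfig, outdir) -> dict:
    """Execute the pipeline and write the report bundle into ``outdir``.

    Returns the machine-readable summary (also written as summary.json).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[str] = []

    def stage(msg):
        log.append(f"[{time.time() - t0:8.2f}s] {msg}")

    summary: dict = {"config_hash": config.hash(), "seed": config.seed}

    if config.data_mode:
        bathy, surveys, obs_all, fps_all = _load_data_inputs(config)
        cams = list(fps_all)
        stage("real-data inputs loaded")
    else:
        bathy = gen_bathymetry(
            plain_depth=config.plain_depth,
            hill_height=config.hill_height,
            hill_sigma=config.hill_sigma,
            extent=config.domain,
            cell_size=config.cell_size,
        )
        stage("bathymetry generated")

        # Fauna exists beyond the surveyed box: pad the generated pattern
        # so footprints at the survey boundary are not edge-truncated.
        pad = PATTERN_EDGE_PAD_M
        region = (-pad, config.domain[0] + pad, -pad, config.domain[1] + pad)
        spec = PointPatternSpec(
            regime=config.regime,
            intensity=config.intensity,
            thomas_sigma=config.thomas_sigma,
            thomas_mean_offspring=config.thomas_mean_offspring,
            hardcore_radius=config.hardcore_radius,
            seed=config.seed,
        )
        pattern = gen_point_pattern(spec, region, bathy)
        stage(f"point pattern generated ({len(pattern)} individuals, {config.regime})")

        surveys = _simulate_surveys(config, bathy)
        stage(f"surveys simulated ({len(surveys)})")

        cams = ["vertical", "oblique"]
        obs_by_cam: dict[str, list[pd.DataFrame]] = {cam: [] for cam in cams}
        for sid, sv in surveys.items():
            for cam in cams:
                obs_by_cam[cam].append(detect_fish(pattern, sv[cam]))
        obs_all = {
            cam: pd.concat(frames, ignore_index=True)
            for cam, frames in obs_by_cam.items()
        }
        fps_all = {
            cam: FootprintSet.concatenate([sv[cam] for sv in surveys.values()])
            for cam in cams
        }
        stage(
            "fish detected (%s)"
            % ", ".join(f"{cam} {len(obs_all[cam])}" for cam in cams)
        )
        summary["n_true_fish"] = int(len(pattern))

    summary["surveys"] = {
        sid: {
            cam: {
                "n_images": len(sv[cam]),
                "area_km2": sv[cam].effort_area_km2(),
                "n_fish": int(len(obs_all[cam][obs_all[cam]["survey_id"] == sid])),
            }
            for cam in cams
        }
        for sid, sv in surveys.items()
    }

    taxa = [t for t in config.taxa_of_interest]

    if config.do_density:
        rows = []
        for cam in cams:
            groups = {"total": fps_all[cam], **split_groups(fps_all[cam], bathy)}
            for gname, fps in groups.items():
                if len(fps) == 0:
                    continue
                gobs = obs_all[cam][obs_all[cam]["image_id"].isin(fps.image_id)]
                for taxon in [None] + taxa:
                    est = dens.bootstrap_density(
                        gobs,
                        fps,
                        n_boot=config.n_boot,
                        seed=config.seed + 7,
                        taxon=taxon,
                        group=f"{cam}/{gname}",
                    )
                    rows.append(dataclasses.asdict(est))
        densities = pd.DataFrame(rows)
        densities.to_csv(outdir / "densities.csv", index=False)
        summary["density"] = {
            r["group"] + "/" + r["taxon"]: {
                "point_density": r["point_density"],
                "ci": [r["ci_low"], r["ci_high"]],
            }
            for r in rows
        }
        ver = [r for r in rows if r["group"] == "vertical/plain" and r["taxon"] == "all"]
        elev = [
            r for r in rows if r["group"] == "vertical/elevated" and r["taxon"] == "all"
        ]
        if ver and elev:
            summary["density"]["plain_vs_elevated_vertical"] = comp = dens.compare_ci(
                _as_est(ver[0]), _as_est(elev[0])
            )
        stage("density tables written")

    if config.do_terrain:
        contours = terr.extract_contours(bathy)
        ks_rows = []
        for cam in cams:
            fps = fps_all[cam]
            dists = terr.distance_to_contour(fps.centre, contours)
            fishy = np.isin(fps.image_id, obs_all[cam]["image_id"].unique())
            rng = np.random.default_rng(config.seed + 11)
            for level, d in dists.items():
                if fishy.sum() == 0 or (~fishy).sum() == 0:
                    continue
                empty = d[~fishy]
                if empty.size > config.ks_empty_subsample:
                    empty = rng.choice(empty, config.ks_empty_subsample, replace=False)
                res = terr.bootstrap_ks(
                    d[fishy], empty, n_boot=config.n_ks_boot, seed=config.seed + 13
                )
                ks_rows.append(
                    {
                        "camera": cam,
                        "level_m": level,
                        "D": res.d,
                        "p": res.p,
                        "n_fish_images": res.n_a,
                        "n_empty_images": res.n_b,
                    }
                )
        ks_df = pd.DataFrame(ks_rows)
        ks_df.to_csv(outdir / "terrain_ks.csv", index=False)
        summary["terrain_ks"] = ks_rows
        stage("terrain KS tests written")

    if config.do_pattern:
        k_frames = []
        quad_rows = []
        broad_ids = [
            sid
            for sid, sv in surveys.items()
            if sv["design"] is None or sv["design"].scale == "broad"
        ]
        for cam in cams:
            for bid in broad_ids:
                sv = surveys[bid]
                obs_b = obs_all[cam][obs_all[cam]["survey_id"] == bid]
                seq = patt.TransectSequence.from_observations(sv[cam], obs_b, taxa=taxa)
                for taxon in ["all"] + taxa:
                    if seq.counts[taxon].sum() < 2:
                        continue
                    res = patt.dispersion_analysis(
                        seq, taxon, n_sim=config.n_sim, seed=config.seed + 17
                    )
                    frame = res.to_frame()
                    frame.insert(0, "taxon", taxon)
                    frame.insert(0, "camera", cam)
                    k_frames.append(frame)
            for sid, sv in surveys.items():
                if sv["design"] is None or sv["design"].scale != "fine":
                    continue
                fps = sv[cam]
                obs_f = obs_all[cam][obs_all[cam]["survey_id"] == sid]
                if len(obs_f) == 0:
                    continue
                cells = patt.quadrat_assign(
                    fps.centre, sv["design"].origin, sv["design"].extent
                )
                counts = dens.counts_per_image(obs_f, fps)
                qr = patt.mc_vmr(
                    cells, counts, n_mc=config.n_mc, seed=config.seed + 19
                )
                quad_rows.append(
                    {
                        "camera": cam,
                        "survey_id": sid,
                        "n_fish": qr.n_fish,
                        "vmr": qr.vmr_obs,
                        "ci_low": qr.ci_low,
                        "ci_high": qr.ci_high,
                        "verdict": qr.verdict,
                    }
                )
        if k_frames:
            pd.concat(k_frames, ignore_index=True).to_csv(
                outdir / "neighbour_k.csv", index=False
            )
            summary["neighbour_k_verdicts"] = {
                f"{f['camera'].iloc[0]}/{f['taxon'].iloc[0]}": f["verdict"].tolist()
                for f in k_frames
            }
        quad_df = pd.DataFrame(quad_rows)
        quad_df.to_csv(outdir / "quadrats.csv", index=False)
        summary["quadrats"] = quad_rows
        stage("dispersion analyses written")

    if config.do_community:
        groups = {cam: (fps_all[cam], obs_all[cam]) for cam in cams}
        try:
            mat, labels = comm.abundance_matrix(
                groups, k=config.n_community_groups, seed=config.seed + 23
            )
            res = comm.anosim(mat, labels, seed=config.seed + 29)
            res_pa = comm.anosim(
                comm.presence_absence(mat), labels, seed=config.seed + 29
            )
            simper_df = comm.simper(mat, labels)
            mat.to_csv(outdir / "abundance_matrix.csv")
            simper_df.to_csv(outdir / "simper.csv", index=False)
            summary["community"] = {
                "anosim": {"R": res.r, "p": res.p, "n_perm": res.n_perm},
                "anosim_presence_absence": {"R": res_pa.r, "p": res_pa.p},
            }
        except ValueError as exc:
            summary["community"] = {"skipped": str(exc)}
        stage("community analyses written")

    stage("done")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    return summary


def split_groups(fps: FootprintSet, bathy: BathymetryGrid) -> dict[str, FootprintSet]:
    parts = dens.split_by_depth(fps, bathy)
    return {k: v for k, v in parts.items() if len(v)}


def _as_est(row: dict) -> dens.DensityEstimate:
    return dens.DensityEstimate(**row)
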