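"""Readers/writers, session bundling and the end-to-end pipeline.

A *session* is an open on-disk bundle (JSON manifest + npz arrays + CSV
exports) holding everything a montage analysis produced: cone coordinates,
density maps, landmarks, scale metadata and an append-only provenance log.
Reloading a saved session reproduces all numeric content bit-exactly (arrays
are stored losslessly; the CSV files are human-readable exports).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import __version__
from .core import ConeSet, ScalarMap, ValidityMask
from .detect import DetectConfig, RAPSConfig, locate_cones, raps_refine
from .eval_metrics import (MatchConfig, chamfer, correction_time, match_cones,
                           scores)
from .preprocess import distance_label
from .synthetic_mosaic import MosaicSpec, SyntheticSample, generate_positions, render
from .topography import (DensityMap, Landmarks, find_landmarks, icd_density,
                         voronoi_density, yellott_density)

__all__ = [
    "read_image", "write_image", "read_cones", "write_cones",
    "Session", "PipelineConfig", "run_pipeline", "save_sample",
]


def read_image(path) -> tuple[np.ndarray, dict]:
    """Load a grayscale 8/16-bit TIFF or PNG, scaled to [0, 1] by bit depth."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel grayscale image, "
            f"got shape {arr.shape} (RGB images are not supported)"
        )
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise ValueError(f"{path.name}: unsupported bit depth {arr.dtype}")
    meta = {"shape": arr.shape, "dtype": str(arr.dtype), "path": str(path)}
    return arr.astype(float) / scale, meta


def write_image(image: np.ndarray, path, bit_depth: int = 16) -> None:
    """Write a [0, 1] float image as 8/16-bit grayscale TIFF or PNG."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        arr = np.round(img * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(img * 255.0).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_cones(path, one_based: bool = False,
               scale_px_per_deg: float | None = None) -> ConeSet:
    """Read cone coordinates from a CSV with an ``x,y`` header.

    Extra columns are ignored; ``one_based=True`` shifts coordinates by -1 to
    the package's 0-based convention.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: CSV must have an 'x,y' header, got {list(df.columns)}")
    xy = np.column_stack([
        pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(),
        pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(),
    ])
    if not np.all(np.isfinite(xy)):
        bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0]) + 2
        raise ValueError(f"{path}: non-numeric coordinate at row {bad}")
    if one_based:
        xy = xy - 1.0
    return ConeSet(xy, scale_px_per_deg=scale_px_per_deg)


def write_cones(cones: ConeSet, path, decimals: int = 4) -> None:
    """Order-preserving CSV writer with fixed decimal formatting."""
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in cones.xy:
            fh.write(f"{x:.{decimals}f},{y:.{decimals}f}\n")


def save_sample(sample: SyntheticSample, out_dir, stem: str) -> None:
    """Write a synthetic sample as image + coordinate CSV + YAML spec sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_image(sample.image, out_dir / f"{stem}.tif", bit_depth=16)
    write_cones(sample.cones, out_dir / f"{stem}.csv")
    with open(out_dir / f"{stem}.yaml", "w") as fh:
        yaml.safe_dump(asdict(sample.spec), fh)


# ---------------------------------------------------------------------------


@dataclass
class Session:
    image_path: str | None = None
    image_sha256: str | None = None
    cones: ConeSet | None = None
    density_maps: dict[str, DensityMap] = field(default_factory=dict)
    landmarks: Landmarks | None = None
    evaluation: dict | None = None
    scale_px_per_deg: float | None = None
    rmf_um_per_deg: float | None = None
    provenance: list[dict] = field(default_factory=list)

    def log(self, stage: str, **params) -> None:
        self.provenance.append({
            "stage": stage,
            "time": datetime.datetime.now().isoformat(timespec="seconds"),
            "version": __version__,
            **params,
        })

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        manifest = {
            "image_path": self.image_path,
            "image_sha256": self.image_sha256,
            "scale_px_per_deg": self.scale_px_per_deg,
            "rmf_um_per_deg": self.rmf_um_per_deg,
            "evaluation": self.evaluation,
            "provenance": self.provenance,
            "density_maps": {},
            "landmarks": None,
        }
        if self.cones is not None:
            arrays["cones_xy"] = self.cones.xy
            write_cones(self.cones, out_dir / "cones.csv")
        for name, dm in self.density_maps.items():
            arrays[f"density_{name}"] = dm.data
            arrays[f"density_{name}_valid"] = dm.valid
            manifest["density_maps"][name] = {
                "method": dm.method, "units": dm.units,
                "grid_step_px": dm.grid_step_px, "origin_px": list(dm.origin_px),
                "scale_px_per_deg": dm.scale_px_per_deg,
            }
            tifffile.imwrite(out_dir / f"density_{name}.tif",
                             dm.data.astype(np.float32))
        if self.landmarks is not None:
            manifest["landmarks"] = {
                "cdc_xy": list(self.landmarks.cdc_xy),
                "cdc_value": self.landmarks.cdc_value,
                "pcd_xy": list(self.landmarks.pcd_xy),
                "pcd_value": self.landmarks.pcd_value,
            }
        np.savez(out_dir / "arrays.npz", **arrays)
        with open(out_dir / "session.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, out_dir) -> "Session":
        out_dir = Path(out_dir)
        with open(out_dir / "session.json") as fh:
            manifest = json.load(fh)
        data = np.load(out_dir / "arrays.npz")
        s = cls(image_path=manifest["image_path"],
                image_sha256=manifest["image_sha256"],
                scale_px_per_deg=manifest["scale_px_per_deg"],
                rmf_um_per_deg=manifest["rmf_um_per_deg"],
                evaluation=manifest["evaluation"],
                provenance=manifest["provenance"])
        if "cones_xy" in data:
            s.cones = ConeSet(data["cones_xy"],
                              scale_px_per_deg=s.scale_px_per_deg)
        for name, meta in manifest["density_maps"].items():
            s.density_maps[name] = DensityMap(
                data=data[f"density_{name}"], valid=data[f"density_{name}_valid"],
                method=meta["method"], scale_px_per_deg=meta["scale_px_per_deg"],
                grid_step_px=meta["grid_step_px"],
                origin_px=tuple(meta["origin_px"]), units=meta["units"],
            )
        if manifest["landmarks"] is not None:
            lm = manifest["landmarks"]
            s.landmarks = Landmarks(cdc_xy=tuple(lm["cdc_xy"]),
                                    cdc_value=lm["cdc_value"],
                                    pcd_xy=tuple(lm["pcd_xy"]),
                                    pcd_value=lm["pcd_value"])
        return s


@dataclass
class PipelineConfig:
    image: str | None = None          # path; or simulate with the spec below
    simulate: MosaicSpec | None = None
    model: str | None = None          # checkpoint path; None => exact-label demo
    gt: str | None = None             # ground-truth CSV for evaluation
    scale_px_per_deg: float = 600.0
    rmf_um_per_deg: float | None = None
    raps: bool = False                # particle system off by default
    density_method: str = "voronoi"
    density_k: int = 150
    grid_step_px: float = 10.0
    detect: DetectConfig = field(default_factory=DetectConfig)
    raps_cfg: RAPSConfig = field(default_factory=RAPSConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    seed: int = 0


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> Session:
    """Erode, predict, locate (optionally refine), evaluate, map topography.

    With ``simulate`` set, the input image and ground truth come from the
    synthetic mosaic generator. Without a model checkpoint, the predicted
    distance transform is replaced by the exact distance label of the ground
    truth (a noise-free stand-in useful for smoke runs); detection then runs
    identically on it.
    """
    from .fcn import load_model, predict as fcn_predict

    session = Session(scale_px_per_deg=cfg.scale_px_per_deg,
                      rmf_um_per_deg=cfg.rmf_um_per_deg)
    session.log("start", seed=cfg.seed)
    gt = None
    if cfg.simulate is not None:
        spec = cfg.simulate
        sample = render(generate_positions(spec), spec)
        image, gt = sample.image, sample.cones
        session.log("simulate", seed=spec.seed, n_cones=len(gt))
    elif cfg.image is not None:
        image, meta = read_image(cfg.image)
        session.image_path = str(cfg.image)
        session.image_sha256 = hashlib.sha256(
            Path(cfg.image).read_bytes()).hexdigest()
        session.log("read_image", **{k: str(v) for k, v in meta.items()})
    else:
        raise ValueError("config needs either an image path or a simulate spec")
    if cfg.gt is not None:
        gt = read_cones(cfg.gt, scale_px_per_deg=cfg.scale_px_per_deg)

    mask = ValidityMask(np.ones(image.shape, dtype=bool))
    if cfg.model is not None:
        model = load_model(cfg.model)
        dist = fcn_predict(model, image, mask)
        session.log("predict", model=str(cfg.model), tile=model.cfg.in_size)
    else:
        if gt is None:
            raise ValueError("without a model checkpoint, ground truth is "
                             "needed to build the demo distance map")
        dist = distance_label(gt, image.shape)
        session.log("distance_label_demo", n_cones=len(gt))

    cones = locate_cones(dist, mask, cfg.detect)
    session.log("locate_cones", n=len(cones),
                threshold=cfg.detect.dist_threshold_px)
    if cfg.raps and len(cones) > 0:
        cones = raps_refine(cones, dist, cfg.raps_cfg)
        session.log("raps_refine", alpha=cfg.raps_cfg.alpha)
    cones.scale_px_per_deg = cfg.scale_px_per_deg
    session.cones = cones

    if gt is not None and len(cones) > 0:
        m = match_cones(cones, gt, cfg.match)
        tpr, fdr, f1 = scores(m)
        session.evaluation = {
            "TP": m.tp, "FP": m.n_fp, "FN": m.n_fn,
            "TPR": tpr, "FDR": fdr, "F1": f1,
            "chamfer_px": chamfer(gt, cones),
            "d_px": m.d_used,
            "correction_min": correction_time(m),
        }
        session.log("evaluate", **{k: float(v) for k, v in
                                   session.evaluation.items()})

    if len(cones) >= cfg.density_k + 10 or cfg.density_method != "voronoi":
        if cfg.density_method == "voronoi":
            dm = voronoi_density(cones, cfg.grid_step_px, k=cfg.density_k,
                                 shape=image.shape)
        elif cfg.density_method == "icd":
            dm = icd_density(cones, cfg.grid_step_px, shape=image.shape)
        elif cfg.density_method == "yellott":
            dm = yellott_density(image, grid_step_px=cfg.grid_step_px,
                                 scale_px_per_deg=cfg.scale_px_per_deg)
        else:
            raise ValueError(f"unknown density method {cfg.density_method!r}")
        session.density_maps[cfg.density_method] = dm
        session.landmarks = find_landmarks(dm)
        session.log("topography", method=cfg.density_method,
                    pcd=session.landmarks.pcd_value)
    if out_dir is not None:
        session.save(out_dir)
    return session
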