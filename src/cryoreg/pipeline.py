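"""End-to-end pipeline driver and run configuration.

Stages: (phantom or file input) -> block-matching affine -> FFD -> one-step
resample -> evaluation metrics -> QC renders.  Reports are deterministic
for a fixed config + seed and carry provenance metadata (config hash,
package version, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import checkerboard
from .blockmatch import AffineTransform, BlockMatchConfig, register_affine_multiscale
from .ffd import FFDConfig, FFDTransform, compose_and_resample, jacobian_det_map, optimize_ffd
from .metrics import BinaryMask, LandmarkSet, dice, landmark_error, mean_surface_distance, volume_difference
from .phantom import PhantomSpec, make_phantom_pair
from .volume_io import Volume, read_volume, write_volume

__all__ = ["PipelineConfig", "run_pipeline", "grid_search_weights"]

WEIGHT_WARN = 0.1   # registration quality degrades beyond this
WEIGHT_REJECT = 0.25


@dataclass
class PipelineConfig:
    """Single-file run configuration; CLI flags override these fields."""

    seed: int = 0
    out_dir: str = "cryoreg_run"
    use_phantom: bool = True
    phantom: dict = field(default_factory=dict)       # PhantomSpec overrides
    ref_path: str | None = None
    mov_path: str | None = None
    init_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    blockmatch: dict = field(default_factory=dict)    # BlockMatchConfig overrides
    ffd: dict = field(default_factory=dict)           # FFDConfig overrides
    run_affine: bool = True
    run_ffd: bool = True
    checkerboard_tile_mm: float = 0.4

    def __post_init__(self) -> None:
        cfg = self.ffd_config()
        self.blockmatch_config()
        for name, w in (("w1", cfg.w1), ("w2", cfg.w2)):
            if w > WEIGHT_REJECT:
                raise ValueError(
                    f"{name}={w} rejected: weights beyond {WEIGHT_REJECT} produce "
                    f"degraded registrations (warning threshold {WEIGHT_WARN})")
        if not self.use_phantom and (self.ref_path is None or self.mov_path is None):
            raise ValueError("non-phantom runs need ref_path and mov_path")

    def ffd_config(self) -> FFDConfig:
        return FFDConfig(**self.ffd)

    def blockmatch_config(self) -> BlockMatchConfig:
        return BlockMatchConfig(**self.blockmatch)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(seed=self.seed, **self.phantom)

    def weight_flags(self) -> list[str]:
        cfg = self.ffd_config()
        flags = []
        if cfg.w1 > WEIGHT_WARN:
            flags.append(f"w1={cfg.w1} exceeds degradation threshold {WEIGHT_WARN}")
        if cfg.w2 > WEIGHT_WARN:
            flags.append(f"w2={cfg.w2} exceeds degradation threshold {WEIGHT_WARN}")
        return flags

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _mask_after_transform(mask_mov: BinaryMask, affine, ffd, ref_like: Volume) -> BinaryMask:
    """Pull a moving-frame mask back onto the reference grid through the recovered maps."""
    vol = Volume(mask_mov.data.astype(float), mask_mov.spacing, mask_mov.origin)
    warped = compose_and_resample(vol, affine, ffd, ref_like)
    return BinaryMask(np.asarray(warped.data) > 0.5, ref_like.spacing, ref_like.origin)


def evaluate_registration(pair, affine, ffd) -> dict:
    """Dice / VD / surface distance / landmark error of a recovered transform on a phantom."""
    report = {}
    masks_mov = pair.organ_masks_mov
    masks_ref = pair.organ_masks_ref
    organs = []
    for m_ref, m_mov in zip(masks_ref, masks_mov):
        m_back = _mask_after_transform(m_mov, affine, ffd, pair.ref)
        organs.append({
            "dice": dice(m_ref, m_back),
            "volume_difference": volume_difference(m_ref, m_back),
            "surface_distance_mm": mean_surface_distance(m_ref, m_back),
        })
    report["organs"] = organs
    mapped = pair.landmarks_ref.points.copy()
    if ffd is not None:
        mapped = ffd.map_points(mapped)
    if affine is not None:
        mapped = affine.apply(mapped)
    mean_err, sd_err, _ = landmark_error(
        LandmarkSet(mapped, pair.landmarks_ref.labels), pair.landmarks_mov)
    report["landmark_error_mean_mm"] = mean_err
    report["landmark_error_sd_mm"] = sd_err
    return report


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Artifacts: ``transform.json``, ``ffd.json``, ``resampled.nii.gz``,
    ``jacobian.nii.gz``, ``report.json``, ``checkerboard.png``, ``log.txt``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage, msg, t0=None):
        line = f"[{stage}] {msg}" + (f" ({time.perf_counter() - t0:.1f}s)" if t0 else "")
        log_lines.append(line)

    report = {
        "provenance": {
            "config_hash": cfg.config_hash(),
            "version": __version__,
            "seed": cfg.seed,
            "weight_flags": cfg.weight_flags(),
        }
    }

    t0 = time.perf_counter()
    pair = None
    if cfg.use_phantom:
        pair = make_phantom_pair(cfg.phantom_spec())
        ref, mov = pair.ref, pair.mov
    else:
        ref = read_volume(cfg.ref_path)
        mov = read_volume(cfg.mov_path)
    log("input", f"ref {ref.shape} mov {mov.shape}", t0)

    init = AffineTransform.from_translation(cfg.init_translation_mm)
    affine = init
    if cfg.run_affine:
        t0 = time.perf_counter()
        affine = register_affine_multiscale(ref, mov, cfg.blockmatch_config(), init)
        affine.to_json(out / "transform.json")
        log("affine", "registered", t0)

    ffd_t = None
    if cfg.run_ffd:
        t0 = time.perf_counter()
        ffd_t = optimize_ffd(ref, mov, affine, cfg.ffd_config())
        ffd_t.to_json(out / "ffd.json")
        trace = [c for level in ffd_t.cost_trace for c in level]
        report["ffd_cost_trace"] = trace
        log("ffd", f"registered, {len(trace)} accepted costs", t0)

    t0 = time.perf_counter()
    resampled = compose_and_resample(mov, affine, ffd_t, ref)
    write_volume(resampled, out / "resampled.nii.gz")
    if ffd_t is not None:
        write_volume(jacobian_det_map(ffd_t), out / "jacobian.nii.gz")
    log("resample", "one-step warp written", t0)

    if pair is not None:
        t0 = time.perf_counter()
        report["affine_only"] = evaluate_registration(pair, affine, None) if cfg.run_affine else None
        report["final"] = evaluate_registration(pair, affine, ffd_t)
        log("evaluate", "metrics computed", t0)

    try:
        import imageio.v3 as iio

        board = checkerboard(ref, resampled, cfg.checkerboard_tile_mm)
        iio.imwrite(out / "checkerboard.png",
                    np.clip(board.data, 0, 255).astype(np.uint8))
    except Exception as exc:  # QC render failures must not void the run
        log("qc", f"checkerboard skipped: {exc}")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def grid_search_weights(cfg: PipelineConfig, w1_values, w2_values) -> pd.DataFrame:
    """Run the FFD stage per (w1, w2) pair and tabulate evaluation metrics.

    Requires a phantom config (evaluation masks come from the generator).
    Rows with a weight beyond the degradation threshold are flagged.
    """
    if not cfg.use_phantom:
        raise ValueError("grid search needs a phantom study with ground-truth masks")
    pair = make_phantom_pair(cfg.phantom_spec())
    init = AffineTransform.from_translation(cfg.init_translation_mm)
    affine = (register_affine_multiscale(pair.ref, pair.mov, cfg.blockmatch_config(), init)
              if cfg.run_affine else init)
    rows = []
    base = cfg.ffd
    for w1 in w1_values:
        for w2 in w2_values:
            fcfg = FFDConfig(**{**base, "w1": float(w1), "w2": float(w2)})
            ffd_t = optimize_ffd(pair.ref, pair.mov, affine, fcfg)
            ev = evaluate_registration(pair, affine, ffd_t)
            organs = ev["organs"]
            rows.append({
                "w1": float(w1),
                "w2": float(w2),
                "dice": float(np.mean([o["dice"] for o in organs])),
                "volume_difference": float(np.mean([o["volume_difference"] for o in organs])),
                "surface_distance_mm": float(np.mean([o["surface_distance_mm"] for o in organs])),
                "landmark_error_mm": ev["landmark_error_mean_mm"],
                "flagged": bool(w1 > WEIGHT_WARN or w2 > WEIGHT_WARN),
            })
    return pd.DataFrame(rows)
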