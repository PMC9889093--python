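"""Stack I/O, manifest handling and the end-to-end pipeline.

Stacks travel as single-channel multipage TIFF (one page per z-plane,
ascending depth) or as an HDF5 dataset; a YAML manifest maps files to
condition, replicate, fluorophore group and plane spacing, and flags the
baseline protocol of each group. ``run_pipeline`` chains
segment -> depth profile -> half-max -> cross-condition normalization ->
baseline comparison and writes every table as CSV plus a run log recording
seeds and each default applied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import compare as _compare
from . import quantify as _quantify
from . import segmentation as _segmentation
from .segmentation import ImageStack, SegmentationMask

__all__ = [
    "Manifest",
    "ManifestEntry",
    "read_stack",
    "write_stack",
    "write_mask",
    "load_manifest",
    "analyze_stack",
    "run_pipeline",
]

log = logging.getLogger("clearquant")

HDF5_DEFAULT_DATASET = "stack"

# Pipeline defaults, logged whenever applied.
DEFAULTS = {
    "threshold_method": "fixed",
    "threshold_value": 0.2,
    "rolling_ball_radius_px": 5,
    "metric": "signal",
    "onset_frac": 0.1,
    "smooth_window": 3,
    "low_pct": 0.1,
    "high_pct": 99.9,
    "ttest_variant": "student",
}


# --------------------------------------------------------------------------
# Stack readers / writers
# --------------------------------------------------------------------------


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multipage TIFF (.tif) or an HDF5 dataset (.h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            # float32 in both formats so the two interchange paths agree bitwise
            ds = f.create_dataset(
                HDF5_DEFAULT_DATASET, data=np.asarray(stack.voxels, dtype=np.float32)
            )
            ds.attrs["plane_spacing_um"] = stack.plane_spacing_um
            ds.attrs["pixel_size_um"] = stack.pixel_size_um
    else:
        tifffile.imwrite(path, np.asarray(stack.voxels, dtype=np.float32))


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as single-channel multipage TIFF (uint8 0/1)."""
    tifffile.imwrite(Path(path), mask.voxels.astype(np.uint8))


def read_stack(
    path,
    dataset: str = HDF5_DEFAULT_DATASET,
    plane_spacing_um: Optional[float] = None,
    pixel_size_um: Optional[float] = None,
    **metadata,
) -> ImageStack:
    """Read a stack from multipage TIFF or HDF5.

    Page order is ascending z. Plane spacing passed here (normally from the
    manifest) overrides anything stored in the file. Multi-channel TIFFs,
    missing HDF5 datasets and empty files raise explicit errors.
    """
    path = Path(path)
    file_spacing = file_pixel = None
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise KeyError(f"HDF5 file {path} has no dataset {dataset!r}")
            ds = f[dataset]
            data = ds[()]
            file_spacing = ds.attrs.get("plane_spacing_um")
            file_pixel = ds.attrs.get("pixel_size_um")
    else:
        data = tifffile.imread(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel stack, got {data.ndim}D data "
            f"with shape {data.shape} (multi-channel files are not supported)"
        )
    if data.shape[0] == 0:
        raise ValueError(f"{path}: stack has zero planes")
    spacing = plane_spacing_um if plane_spacing_um is not None else file_spacing
    pixel = pixel_size_um if pixel_size_um is not None else file_pixel
    return ImageStack(
        voxels=data.astype(np.float64),
        plane_spacing_um=float(spacing) if spacing is not None else 5.0,
        pixel_size_um=float(pixel) if pixel is not None else 5.0,
        **metadata,
    )


# --------------------------------------------------------------------------
# Manifest
# --------------------------------------------------------------------------

_ENTRY_KEYS = {
    "path",
    "condition_id",
    "replicate_id",
    "fluorophore_group",
    "plane_spacing_um",
    "baseline",
    "mask_path",
}
_GLOBAL_KEYS = {
    "samples",
    "threshold_method",
    "threshold_value",
    "rolling_ball_radius_px",
    "metric",
    "seed",
    "ttest_variant",
    "simulate",
}


@dataclass
class ManifestEntry:
    path: str
    condition_id: str
    replicate_id: str
    fluorophore_group: str = "ch0"
    plane_spacing_um: float = 5.0
    baseline: bool = False
    mask_path: Optional[str] = None

    @property
    def sample_id(self) -> str:
        return f"{self.condition_id}/{self.replicate_id}"


@dataclass
class Manifest:
    """Validated experiment description: entries plus global settings."""

    entries: List[ManifestEntry]
    settings: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest has no samples")
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ValueError(f"duplicate file paths in manifest: {dupes}")
        for e in self.entries:
            if e.plane_spacing_um <= 0:
                raise ValueError(
                    f"entry {e.sample_id}: plane_spacing_um must be > 0"
                )
        for group, conds in self.baselines_by_group().items():
            if len(conds) != 1:
                raise ValueError(
                    f"fluorophore group {group!r} must flag exactly one "
                    f"baseline condition, found {sorted(conds) or 'none'}"
                )

    def baselines_by_group(self) -> Dict[str, set]:
        groups: Dict[str, set] = {}
        for e in self.entries:
            groups.setdefault(e.fluorophore_group, set())
            if e.baseline:
                groups[e.fluorophore_group].add(e.condition_id)
        return groups


def load_manifest(path) -> Manifest:
    """Load and validate a YAML manifest; unknown keys warn, not fail."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    for key in raw:
        if key not in _GLOBAL_KEYS:
            warnings.warn(f"manifest: ignoring unknown key {key!r}", stacklevel=2)
    entries = []
    for item in raw.get("samples", []):
        for key in item:
            if key not in _ENTRY_KEYS:
                warnings.warn(
                    f"manifest sample: ignoring unknown key {key!r}", stacklevel=2
                )
        entries.append(
            ManifestEntry(**{k: v for k, v in item.items() if k in _ENTRY_KEYS})
        )
    settings = {k: v for k, v in raw.items() if k in _GLOBAL_KEYS and k != "samples"}
    applied = {k: v for k, v in DEFAULTS.items() if k not in settings}
    if applied:
        log.info("manifest defaults applied: %s", applied)
    return Manifest(entries=entries, settings=settings)


# --------------------------------------------------------------------------
# Single-sample analysis and the full pipeline
# --------------------------------------------------------------------------


def analyze_stack(
    stack: ImageStack,
    mask: Optional[SegmentationMask] = None,
    radius_px: int = DEFAULTS["rolling_ball_radius_px"],
    threshold_method: str = DEFAULTS["threshold_method"],
    threshold_value: Optional[float] = DEFAULTS["threshold_value"],
    metric: str = DEFAULTS["metric"],
    onset_frac: float = DEFAULTS["onset_frac"],
    smooth_window: int = DEFAULTS["smooth_window"],
):
    """Segment (unless a mask is supplied), profile, and find half-max.

    Returns ``(profile, half_max_result)``. This is the per-sample unit the
    pipeline runs for every manifest entry.
    """
    if mask is None:
        mask = _segmentation.segment_stack(
            stack,
            radius_px=radius_px,
            method=threshold_method,
            value=threshold_value,
        )
    profile = _quantify.plane_metrics(stack, mask)
    start = _quantify.find_start_plane(
        profile, metric=metric, onset_frac=onset_frac, smooth_window=smooth_window
    )
    result = _quantify.half_max_depth(profile, metric=metric, start_plane=start)
    return profile, result


def _profile_frame(profile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "depth_um": profile.depth_um,
            "fraction": profile.fraction,
            "signal": profile.signal,
            "noise": profile.noise,
            "snr": profile.snr,
        }
    )


def run_pipeline(manifest: Manifest, out_dir, simulate_seed: Optional[int] = None):
    """Run the full analysis for every manifest entry and write reports.

    For each sample: segment (or import its mask) -> per-plane metrics ->
    half-max depth; then normalize scores within each fluorophore group and
    t-test every condition against its baseline. Per-sample failures are
    logged and listed in the report without aborting the remaining samples.

    Returns a dict report; raises nothing for per-sample errors but the
    report's ``failed`` list is non-empty when any sample failed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = dict(DEFAULTS)
    settings.update(manifest.settings)
    run_log: Dict[str, object] = {
        "settings": {k: settings[k] for k in sorted(settings)},
        "defaults_applied": sorted(k for k in DEFAULTS if k not in manifest.settings),
        "n_samples": len(manifest.entries),
        "failed": [],
    }
    profiles, halfmax, failed = [], {}, []
    for entry in manifest.entries:
        try:
            stack = read_stack(
                entry.path,
                plane_spacing_um=entry.plane_spacing_um,
                channel_label=entry.fluorophore_group,
                condition_id=entry.condition_id,
                replicate_id=entry.replicate_id,
            )
            mask = None
            if entry.mask_path:
                mask = _segmentation.import_mask(entry.mask_path)
                if mask.voxels.shape != stack.voxels.shape:
                    raise ValueError(
                        f"mask shape {mask.voxels.shape} != stack shape "
                        f"{stack.voxels.shape}"
                    )
            profile, result = analyze_stack(
                stack,
                mask=mask,
                radius_px=int(settings["rolling_ball_radius_px"]),
                threshold_method=str(settings["threshold_method"]),
                threshold_value=settings["threshold_value"],
                metric=str(settings["metric"]),
            )
            profiles.append(profile)
            halfmax[entry.sample_id] = (entry, result)
            safe = entry.sample_id.replace("/", "_")
            _profile_frame(profile).to_csv(out_dir / f"profile_{safe}.csv", index=False)
        except Exception as exc:  # per-sample isolation
            log.error("sample %s failed: %s", entry.sample_id, exc)
            failed.append({"sample": entry.sample_id, "error": str(exc)})
    run_log["failed"] = failed

    # normalized staining-quality scores, one heatmap matrix per group
    groups = sorted({p.fluorophore_group for p in profiles})
    if profiles:
        scores = _quantify.normalize_across_conditions(profiles, metric="fraction")
        for group in groups:
            gscores = [s for s in scores if s.fluorophore_group == group]
            _compare.export_heatmap_matrix(
                gscores, out_dir / f"heatmap_{group}.csv"
            )

    # per-condition summaries vs baseline, within each fluorophore group
    summary_rows = []
    for group in groups:
        entries_g = [
            (e, r) for e, r in halfmax.values() if e.fluorophore_group == group
        ]
        values: Dict[str, List[float]] = {}
        baseline_cond = None
        for e, r in entries_g:
            values.setdefault(e.condition_id, []).append(r.half_max_depth_um)
            if e.baseline:
                baseline_cond = e.condition_id
        if baseline_cond is None or baseline_cond not in values:
            continue
        summaries = _compare.compare_conditions(
            values, baseline=baseline_cond, variant=str(settings["ttest_variant"])
        )
        for s in summaries:
            summary_rows.append(
                {
                    "fluorophore_group": group,
                    "condition": s.condition_id,
                    "baseline": s.baseline_flag,
                    "n": len(s.replicate_values),
                    "mean_um": s.mean_um,
                    "sem_um": s.sem_um,
                    "t": s.t,
                    "df": s.df,
                    "p_vs_baseline": s.p_vs_baseline,
                    "label": s.sig_label,
                }
            )
    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(out_dir / "condition_summary.csv", index=False)
    if simulate_seed is not None:
        run_log["seed"] = int(simulate_seed)
    with open(out_dir / "run_log.json", "w") as f:
        json.dump(run_log, f, indent=2, sort_keys=True)
    return {
        "summary": summary_df,
        "profiles": profiles,
        "halfmax": {k: r for k, (e, r) in halfmax.items()},
        "failed": failed,
    }
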