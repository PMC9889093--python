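"""Depth profiles, staining-quality scores and half-max penetration depth.

Given a stack and its segmentation mask, each z-plane yields four numbers:
the fraction of segmented ("indexed") voxels, the mean intensity inside the
mask (signal), the mean intensity outside it (noise), and their ratio (SNR).
The per-plane series as a function of depth is the pipeline's central
intermediate. From it come the two headline statistics:

* the **half-max depth** — the depth, measured from the detected tissue
  surface, at which the staining metric first falls to half of its maximum;
  deeper is better antibody penetration;
* the **normalized staining-quality score** — each per-plane value divided
  by the single maximum across all conditions sharing a fluorophore, so
  protocols can be compared on a common [0, 1] scale.

Undefined values (e.g. signal on a plane whose mask is empty) are NaN and
are skipped, never treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .segmentation import ImageStack, SegmentationMask

__all__ = [
    "DepthProfile",
    "HalfMaxResult",
    "NormalizedScore",
    "plane_metrics",
    "find_start_plane",
    "half_max_depth",
    "normalize_across_conditions",
    "figure_of_merit",
]


@dataclass
class DepthProfile:
    """Per-plane staining metrics against depth.

    All series share one length (n_planes). ``signal``/``snr`` are NaN on
    planes with an empty mask; ``noise`` is NaN on all-mask planes; ``snr``
    is also NaN where noise is 0.
    """

    depth_um: np.ndarray
    fraction: np.ndarray
    signal: np.ndarray
    noise: np.ndarray
    snr: np.ndarray
    condition_id: str = ""
    replicate_id: str = ""
    fluorophore_group: str = ""

    def __post_init__(self) -> None:
        lengths = {len(self.depth_um), len(self.fraction), len(self.signal),
                   len(self.noise), len(self.snr)}
        if len(lengths) != 1:
            raise ValueError("all profile series must have equal length")

    @property
    def n_planes(self) -> int:
        return len(self.depth_um)

    @property
    def plane_spacing_um(self) -> float:
        if self.n_planes < 2:
            return float("nan")
        return float(self.depth_um[1] - self.depth_um[0])

    def series(self, metric: str) -> np.ndarray:
        if metric not in ("signal", "fraction", "noise", "snr"):
            raise ValueError(f"unknown metric {metric!r}")
        return getattr(self, metric)


@dataclass
class HalfMaxResult:
    """Half-max depth of one sample's profile.

    ``half_max_depth_um`` is measured from the start plane and is NaN when
    the metric never falls below half of its maximum within the stack.
    """

    metric: str
    start_plane: int
    max_value: float
    half_max_depth_um: float
    condition_id: str = ""
    replicate_id: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.half_max_depth_um)


@dataclass
class NormalizedScore:
    """Per-plane values scaled by the cross-condition group maximum."""

    depth_um: np.ndarray
    values: np.ndarray
    reference_max: float
    fluorophore_group: str = ""
    condition_id: str = ""
    replicate_id: str = ""


def plane_metrics(stack: ImageStack, mask: SegmentationMask) -> DepthProfile:
    """Per-plane fraction / signal / noise / SNR for a (stack, mask) pair.

    fraction = segmented voxels ÷ total voxels in the plane;
    signal = mean intensity over mask voxels (NaN if the plane's mask is
    empty); noise = mean over non-mask voxels; snr = signal / noise.
    """
    v = stack.voxels
    m = mask.voxels
    if v.shape != m.shape:
        raise ValueError(
            f"stack shape {v.shape} does not match mask shape {m.shape}"
        )
    plane_size = v.shape[1] * v.shape[2]
    n_in = m.sum(axis=(1, 2)).astype(np.float64)
    n_out = plane_size - n_in
    sum_in = (v * m).sum(axis=(1, 2))
    sum_all = v.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        signal = np.where(n_in > 0, sum_in / np.where(n_in > 0, n_in, 1), np.nan)
        noise = np.where(n_out > 0, (sum_all - sum_in) / np.where(n_out > 0, n_out, 1), np.nan)
        snr = np.where(np.isfinite(signal) & np.isfinite(noise) & (noise > 0),
                       signal / np.where(noise > 0, noise, 1), np.nan)
    return DepthProfile(
        depth_um=stack.depths_um.astype(np.float64),
        fraction=n_in / plane_size,
        signal=signal,
        noise=noise,
        snr=snr,
        condition_id=stack.condition_id,
        replicate_id=stack.replicate_id,
        fluorophore_group=stack.channel_label,
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edges; NaN treated as 0."""
    x = np.nan_to_num(values.astype(np.float64), nan=0.0)
    if window <= 1:
        return x
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def find_start_plane(
    profile: DepthProfile,
    metric: str = "signal",
    onset_frac: float = 0.1,
    smooth_window: int = 3,
) -> int:
    """Detect the tissue surface: first plane with appreciable staining.

    The metric series is smoothed by a centered moving average (edges
    truncated) and the start plane is the first one whose smoothed value
    reaches ``onset_frac`` of the global smoothed maximum. Planes of
    mounting medium above the tissue therefore do not inflate depth
    measurements. An all-zero profile starts at plane 0.
    """
    if profile.n_planes == 0:
        raise ValueError("empty profile")
    smoothed = _smooth(profile.series(metric), smooth_window)
    peak = smoothed.max()
    if peak <= 0:
        return 0
    idx = np.nonzero(smoothed >= onset_frac * peak)[0]
    return int(idx[0])


def half_max_depth(
    profile: DepthProfile, metric: str = "signal", start_plane: int = 0
) -> HalfMaxResult:
    """Depth at which the staining metric falls to half of its maximum.

    Only planes at or after ``start_plane`` are considered, NaN planes are
    skipped. The maximum is located first; then the first pair of
    consecutive defined planes at or after it where the metric crosses
    0.5 × max from above is found, and the crossing depth is linearly
    interpolated between them. Depth is reported in µm relative to the
    start plane. Profiles that never cross return NaN with the maximum
    recorded.
    """
    if not (0 <= start_plane < profile.n_planes):
        raise ValueError(
            f"start_plane {start_plane} outside [0, {profile.n_planes})"
        )
    values = profile.series(metric)[start_plane:]
    depths = profile.depth_um[start_plane:]
    defined = np.isfinite(values)
    if not defined.any():
        raise ValueError(f"metric {metric!r} undefined at every plane")
    vals = values[defined]
    deps = depths[defined]
    i_max = int(np.argmax(vals))
    max_value = float(vals[i_max])
    half = 0.5 * max_value
    depth = float("nan")
    for i in range(i_max, len(vals) - 1):
        if vals[i] >= half > vals[i + 1]:
            frac = (vals[i] - half) / (vals[i] - vals[i + 1])
            crossing = deps[i] + frac * (deps[i + 1] - deps[i])
            depth = float(crossing - depths[0])
            break
    return HalfMaxResult(
        metric=metric,
        start_plane=int(start_plane),
        max_value=max_value,
        half_max_depth_um=depth,
        condition_id=profile.condition_id,
        replicate_id=profile.replicate_id,
    )


def normalize_across_conditions(
    profiles: Iterable[DepthProfile],
    metric: str = "fraction",
    group_by: str = "fluorophore_group",
) -> list:
    """Scale per-plane values by the single maximum across each group.

    Within every fluorophore group, all planes of all profiles share one
    reference maximum, so the best plane of the best condition scores 1 and
    everything else is comparable to it. An all-zero group normalizes to
    zeros with a warning.
    """
    import warnings

    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to normalize")
    groups: dict = {}
    for p in profiles:
        groups.setdefault(getattr(p, group_by), []).append(p)
    out = []
    for key, members in groups.items():
        ref = max(
            (float(np.nanmax(m.series(metric))) for m in members
             if np.isfinite(m.series(metric)).any()),
            default=0.0,
        )
        if ref <= 0:
            warnings.warn(
                f"group {key!r}: all-zero {metric} series, scores set to 0",
                stacklevel=2,
            )
        for m in members:
            vals = np.nan_to_num(m.series(metric), nan=0.0)
            scores = vals / ref if ref > 0 else np.zeros_like(vals)
            out.append(
                NormalizedScore(
                    depth_um=m.depth_um.copy(),
                    values=scores,
                    reference_max=ref,
                    fluorophore_group=key,
                    condition_id=m.condition_id,
                    replicate_id=m.replicate_id,
                )
            )
    return out


def figure_of_merit(profile: DepthProfile, distribution: str = "constant"):
    """Select the per-plane quality series for a given antigen distribution.

    Antigens spread uniformly through the depth of imaging (e.g. cortical
    NeuN) can be scored by the segmented area per plane; antigens with a
    non-constant distribution are better scored by the area-normalized mean
    staining intensity. Pure function: the profile is not modified.
    """
    if distribution == "constant":
        return profile.fraction.copy(), "fraction"
    if distribution == "nonconstant":
        return profile.signal.copy(), "signal"
    raise ValueError(f"distribution must be 'constant' or 'nonconstant', got {distribution!r}")
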