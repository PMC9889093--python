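"""Segmentation of cleared-tissue fluorescence stacks.

Turns a raw Z-stack into a binary segmentation mask via whole-stack
percentile normalization, per-plane rolling-ball background estimation and
thresholding, or imports an externally produced mask / probability map
(e.g. an Ilastik pixel-classifier export saved as multipage TIFF).

Array convention: stacks and masks are ``(nz, ny, nx)`` with z (depth) as
axis 0, matching multipage-TIFF page order.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.restoration import rolling_ball as _paraboloid_rolling_ball

__all__ = [
    "ImageStack",
    "SegmentationMask",
    "normalize_stack",
    "rolling_ball_background",
    "subtract_background",
    "threshold_mask",
    "segment_stack",
    "import_mask",
]


@dataclass
class ImageStack:
    """A 3D fluorescence intensity grid with physical metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities in arbitrary units; must be finite.
    plane_spacing_um : float
        Physical spacing between consecutive z-planes, in micrometres.
    pixel_size_um : float
        Lateral pixel size, in micrometres.
    channel_label : str
        Fluorophore / channel name (used to group samples for
        cross-condition normalization).
    condition_id, replicate_id : str
        Sample identity within the experiment.
    blind_code : str, optional
        Random code assigned during blinding.
    meta : dict
        Free-form provenance (e.g. ground-truth attenuation parameters for
        synthetic stacks).
    """

    voxels: np.ndarray
    plane_spacing_um: float = 5.0
    pixel_size_um: float = 5.0
    channel_label: str = ""
    condition_id: str = ""
    replicate_id: str = ""
    blind_code: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"stack must be 3D (nz, ny, nx), got shape {self.voxels.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite intensities")
        if self.plane_spacing_um <= 0:
            raise ValueError("plane_spacing_um must be > 0")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def depths_um(self) -> np.ndarray:
        """Depth of each plane (µm), plane 0 at depth 0."""
        return np.arange(self.n_planes) * self.plane_spacing_um


@dataclass
class SegmentationMask:
    """Binary voxel mask congruent with a parent stack.

    ``source`` records whether the mask came from the internal
    normalize/subtract/threshold path or was imported from an external
    segmentation tool; ``threshold_used`` is the scalar threshold applied,
    or the string ``"external"`` for imported binary masks.
    """

    voxels: np.ndarray
    source: str = "internal"
    threshold_used: object = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            uniq = np.unique(self.voxels)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask voxels must be strictly binary")
            self.voxels = self.voxels.astype(bool)
        if self.source not in ("internal", "imported"):
            raise ValueError(f"unknown mask source {self.source!r}")


def normalize_stack(
    stack: ImageStack, low_pct: float = 0.1, high_pct: float = 99.9
) -> ImageStack:
    """Rescale intensities so whole-stack percentiles map to [0, 1].

    The low/high percentiles are computed over the *entire* stack — not
    per plane — so that depth-dependent attenuation survives normalization.
    Values outside the percentile window are clipped. A constant stack
    (equal percentiles) yields an all-zero stack with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    v = stack.voxels.astype(np.float64)
    lo, hi = np.percentile(v, [low_pct, high_pct])
    if hi == lo:
        warnings.warn(
            "constant stack: percentile bounds coincide, returning zeros",
            stacklevel=2,
        )
        out = np.zeros_like(v)
    else:
        out = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return dataclasses.replace(stack, voxels=out)


def rolling_ball_background(
    plane: np.ndarray, radius_px: int, method: str = "opening"
) -> np.ndarray:
    """Estimate the smooth background of a single 2D plane.

    method="opening" (default): grayscale morphological opening with a flat
    ball-shaped (disk) structuring element of the given radius — erosion
    followed by dilation. The result never exceeds the input and the
    operation is idempotent. method="paraboloid" uses the classic
    intensity-space rolling-ball of Sternberg instead.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError(f"plane must be 2D, got shape {plane.shape}")
    radius_px = int(radius_px)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > plane.shape[0] and radius_px > plane.shape[1]:
        raise ValueError(
            f"radius {radius_px} exceeds both image dimensions {plane.shape}"
        )
    if method == "paraboloid":
        return _paraboloid_rolling_ball(plane, radius=radius_px)
    if method != "opening":
        raise ValueError(f"unknown rolling-ball method {method!r}")
    footprint = disk(radius_px)
    eroded = ndimage.grey_erosion(plane, footprint=footprint, mode="nearest")
    return ndimage.grey_dilation(eroded, footprint=footprint, mode="nearest")


def subtract_background(
    stack: ImageStack, radius_px: int, method: str = "opening"
) -> ImageStack:
    """Subtract the per-plane rolling-ball background, clipping at zero.

    Runs in 2D plane by plane: background structure varies slowly with
    depth, and a per-plane estimate cannot borrow intensity across the
    attenuation gradient.
    """
    v = stack.voxels.astype(np.float64)
    out = np.empty_like(v)
    for z in range(v.shape[0]):
        bg = rolling_ball_background(v[z], radius_px, method=method)
        out[z] = np.clip(v[z] - bg, 0.0, None)
    return dataclasses.replace(stack, voxels=out)


def threshold_mask(
    stack: ImageStack, method: str = "otsu", value: Optional[float] = None
) -> SegmentationMask:
    """Binarize a stack: foreground are voxels *strictly above* threshold.

    method="fixed" uses the supplied ``value`` (required, in (0, 1) for
    normalized stacks); method="otsu" picks the threshold maximizing
    between-class variance on the whole-stack 256-bin histogram.
    """
    if method == "fixed":
        if value is None:
            raise ValueError("method='fixed' requires a threshold value")
        t = float(value)
    elif method == "otsu":
        v = stack.voxels
        if np.min(v) == np.max(v):
            t = float(np.min(v))  # degenerate: all voxels equal -> empty mask
        else:
            t = float(threshold_otsu(v.ravel(), nbins=256))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return SegmentationMask(
        voxels=stack.voxels > t, source="internal", threshold_used=t
    )


def segment_stack(
    stack: ImageStack,
    radius_px: int = 5,
    method: str = "otsu",
    value: Optional[float] = None,
    low_pct: float = 0.1,
    high_pct: float = 99.9,
    rolling_ball_method: str = "opening",
) -> SegmentationMask:
    """Full internal path: normalize -> subtract background -> threshold."""
    s = normalize_stack(stack, low_pct=low_pct, high_pct=high_pct)
    s = subtract_background(s, radius_px, method=rolling_ball_method)
    return threshold_mask(s, method=method, value=value)


def import_mask(path, prob_threshold: float = 0.5) -> SegmentationMask:
    """Load an externally produced mask or probability map.

    Accepts a single-channel multipage TIFF containing either a binary
    mask (any dtype whose values are exactly {0, 1} — or {0, 255} for
    8-bit exports) or per-voxel foreground probabilities in [0, 1], which
    are binarized at ``prob_threshold`` with strict inequality.
    """
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"expected single-channel multipage TIFF, got {data.ndim}D data "
            f"with shape {data.shape}"
        )
    uniq = np.unique(data)
    if np.all(np.isin(uniq, (0, 1))) or np.all(np.isin(uniq, (0, 255))):
        mask = data > 0
        return SegmentationMask(voxels=mask, source="imported", threshold_used="external")
    if not np.issubdtype(data.dtype, np.floating):
        raise ValueError(
            "integer mask file contains values other than {0,1}/{0,255}; "
            "cannot interpret as binary mask or probability map"
        )
    if data.min() < 0 or data.max() > 1:
        raise ValueError(
            f"probability map values outside [0, 1]: range "
            f"[{data.min():g}, {data.max():g}]"
        )
    return SegmentationMask(
        voxels=data > prob_threshold, source="imported", threshold_used=float(prob_threshold)
    )
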