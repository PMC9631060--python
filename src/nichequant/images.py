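"""Calibrated image stacks and the preprocessing primitives applied before
every quantification stage.

The conventions used throughout the package are fixed here: 0-based indices,
axis order ``(z, y, x)`` for volumes and ``(y, x)`` for planar images, and
physical calibration carried as a per-axis spacing in micrometres.  Centroids
and distances are always reported in micrometres (index times spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops


class ValidationError(ValueError):
    """A precondition on inputs or parameters was violated."""


class DegenerateInputError(ValidationError):
    """The input is structurally valid but carries no usable signal
    (empty mask, constant image, zero denominator)."""


def _as_spacing(spacing, ndim: int) -> tuple[float, ...]:
    if np.isscalar(spacing):
        spacing = (float(spacing),) * ndim
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) != ndim:
        raise ValidationError(
            f"spacing has {len(spacing)} entries for a {ndim}-D image"
        )
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be positive, got {spacing}")
    return spacing


@dataclass
class ImageStack:
    """A 2D ``(y, x)`` or 3D ``(z, y, x)`` intensity grid with µm calibration.

    Parameters
    ----------
    data : ndarray
        Nonnegative finite intensities.
    spacing : float or sequence of float
        Physical size of one step along each axis, in µm.  A scalar is
        broadcast to every axis.
    channel_name : str
        Free-text channel label (e.g. ``"CD31"``, ``"RFP"``).
    """

    data: np.ndarray
    spacing: tuple[float, ...] = 1.0
    channel_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValidationError(
                f"image data must be 2D or 3D, got {self.data.ndim}D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("image contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("image contains negative intensities")
        self.spacing = _as_spacing(self.spacing, self.data.ndim)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def pixel_area_um2(self) -> float:
        """Physical area of one in-plane pixel (product of the last two
        spacing entries)."""
        return self.spacing[-2] * self.spacing[-1]

    @property
    def voxel_volume_um3(self) -> float:
        if self.ndim != 3:
            raise ValidationError("voxel volume is defined for 3D stacks only")
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


@dataclass
class BinaryMask:
    """Boolean foreground mask sharing :class:`ImageStack` axis and spacing
    semantics."""

    data: np.ndarray
    spacing: tuple[float, ...] = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim not in (2, 3):
            raise ValidationError(
                f"mask must be 2D or 3D, got {self.data.ndim}D"
            )
        self.spacing = _as_spacing(self.spacing, self.data.ndim)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.spacing[-2] * self.spacing[-1]

    def foreground_area_um2(self) -> float:
        """Total foreground area (2D masks), in µm²."""
        if self.ndim != 2:
            raise ValidationError("foreground area is defined for 2D masks")
        return float(self.data.sum()) * self.pixel_area_um2


@dataclass
class LabeledObjects:
    """Connected objects as an integer label grid plus a per-object table.

    ``labels`` uses 0 for background and the consecutive integers 1..N for
    objects.  ``table`` carries one row per object: ``label``, centroid
    coordinates in µm (``centroid_z_um`` only for 3D), and ``area_um2``
    (volume in µm³ for 3D grids, kept under the same column name used by the
    CSV interface).
    """

    labels: np.ndarray
    spacing: tuple[float, ...]
    table: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing = _as_spacing(self.spacing, self.labels.ndim)
        if self.table is None:
            self.table = _object_table(self.labels, self.spacing)
        grid_ids = set(np.unique(self.labels)) - {0}
        table_ids = set(self.table["label"].tolist())
        if grid_ids != table_ids:
            raise ValidationError("label grid and table ids disagree")
        n = len(table_ids)
        if table_ids and table_ids != set(range(1, n + 1)):
            raise ValidationError("label ids must be consecutive 1..N")

    @property
    def n_objects(self) -> int:
        return len(self.table)


def _object_table(labels: np.ndarray, spacing) -> pd.DataFrame:
    rows = []
    px_measure = float(np.prod(spacing))
    for rp in regionprops(labels):
        centroid_um = tuple(c * s for c, s in zip(rp.centroid, spacing))
        row = {"label": rp.label}
        axes = ("centroid_z_um", "centroid_y_um", "centroid_x_um")[-labels.ndim:]
        row.update(dict(zip(axes, centroid_um)))
        row["area_um2"] = rp.area * px_measure
        rows.append(row)
    cols = ["label"]
    cols += ["centroid_z_um"] if labels.ndim == 3 else []
    cols += ["centroid_y_um", "centroid_x_um", "area_um2"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# I/O


def read_stack(path, spacing, channel_name: str = "") -> ImageStack:
    """Read a single- or multi-page TIFF as a calibrated stack.

    Multi-page files come back as ``(z, y, x)``; single-page as ``(y, x)``.
    Pixel values are preserved bit-exactly.
    """
    try:
        data = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"could not read TIFF {path!s}: {exc}") from exc
    data = np.squeeze(data)
    return ImageStack(data=data, spacing=spacing, channel_name=channel_name)


def write_stack(path, stack: ImageStack | BinaryMask) -> None:
    """Write a stack or mask as TIFF; masks are stored 8-bit as {0, 255}."""
    data = stack.data
    if data.dtype == bool:
        data = (data.astype(np.uint8)) * 255
    tifffile.imwrite(str(path), data)


# ---------------------------------------------------------------------------
# Preprocessing primitives


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum intensity projection of a 3D stack onto the (y, x) plane."""
    if stack.ndim != 3:
        raise ValidationError("max_project requires a 3D stack")
    return ImageStack(
        data=stack.data.max(axis=0),
        spacing=stack.spacing[1:],
        channel_name=stack.channel_name,
    )


def _ball_footprint_2d(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def rolling_ball_subtract(image: ImageStack, radius_um: float) -> ImageStack:
    """Subtract a smoothly varying background estimated with a rolling ball.

    The background is the grey-scale morphological opening of the image with
    a disk of the stated physical radius — the standard equivalent of the
    ImageJ rolling-ball filter.  Features smaller than the ball survive;
    broad gradients are removed.  Output is clipped at zero.
    """
    if image.ndim != 2:
        raise ValidationError("rolling_ball_subtract operates on 2D images")
    if radius_um <= 0:
        raise ValidationError("radius_um must be positive")
    px = min(image.spacing)
    radius_px = radius_um / px
    if radius_px < 1:
        raise ValidationError(
            f"rolling-ball radius {radius_um} µm is below one pixel "
            f"({px} µm); use a larger radius"
        )
    footprint = _ball_footprint_2d(radius_px)
    background = ndi.grey_opening(image.data, footprint=footprint)
    out = np.clip(image.data.astype(float) - background, 0, None)
    return replace(image, data=out)


def enhance_contrast(image: ImageStack, saturated: float) -> ImageStack:
    """Linear contrast stretch saturating a fixed fraction of pixels.

    ``saturated`` is the total fraction of pixels allowed to clip, split
    equally between the low and high tails (the ImageJ "Enhance Contrast"
    convention; its dialog value 0.35 means 0.35 %, i.e. ``saturated=0.0035``).
    The mapping is monotone non-decreasing and the output spans the input's
    original value range.  Constant images pass through unchanged.
    """
    if not (0 <= saturated < 1):
        raise ValidationError("saturated fraction must lie in [0, 1)")
    data = image.data.astype(float)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax == vmin:
        return replace(image, data=data)
    flat = np.sort(data, axis=None)
    k = int(saturated / 2 * flat.size)
    if k == 0:
        lo, hi = vmin, vmax
    else:
        # midpoint anchors: exactly the k lowest / k highest ranked pixels
        # saturate, the rank-(k+1) pixel keeps a distinct value
        lo = (flat[k - 1] + flat[k]) / 2.0
        hi = (flat[flat.size - k] + flat[flat.size - 1 - k]) / 2.0
    if hi == lo:  # heavy ties: fall back to the full range
        lo, hi = vmin, vmax
    out = (np.clip(data, lo, hi) - lo) / (hi - lo) * (vmax - vmin) + vmin
    return replace(image, data=out)


def binarize(
    image: ImageStack,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Threshold an image into a foreground mask (strictly above threshold).

    ``method="fixed"`` uses the supplied threshold; ``method="otsu"`` picks
    the threshold maximizing between-class variance — the reproducible
    default standing in for interactive manual thresholding.
    """
    if method == "fixed":
        if threshold is None:
            raise ValidationError("fixed thresholding requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        if np.unique(image.data).size < 2:
            raise DegenerateInputError(
                "Otsu thresholding needs at least two distinct intensities"
            )
        t = float(threshold_otsu(image.data))
    else:
        raise ValidationError(f"unknown binarization method {method!r}")
    return BinaryMask(data=image.data > t, spacing=image.spacing)


_CONNECTIVITY = {"face": 1, "full": None}  # None → ndim (resolved per mask)


def label_objects(
    mask: BinaryMask,
    min_area_um2: float = 0.0,
    connectivity: str = "full",
) -> LabeledObjects:
    """Connected-component labeling with a physical minimum-size filter.

    Components smaller than ``min_area_um2`` (µm², or µm³ for volumes) are
    dropped and the remaining objects relabeled 1..N in scan order.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValidationError("connectivity must be 'face' or 'full'")
    conn = _CONNECTIVITY[connectivity] or mask.ndim
    labels = _cc_label(mask.data, connectivity=conn)
    px_measure = float(np.prod(mask.spacing))
    if min_area_um2 > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts * px_measure >= min_area_um2)
        keep = keep[keep > 0]
        remap = np.zeros(counts.size, dtype=labels.dtype)
        remap[keep] = np.arange(1, keep.size + 1)
        labels = remap[labels]
    return LabeledObjects(labels=labels, spacing=mask.spacing)
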