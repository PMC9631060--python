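"""Spheroid invasion quantification from binarized tumor-channel images.

A spheroid sits at the centre of the field and tumor cells invade outward.
The radial profile records, for each annulus around the spheroid centroid,
the fraction of pixels occupied by tumor signal — 1 inside the spheroid
body, decaying to 0 far away.  From it come the characteristic invasion
radii r_i (the radius where the profile falls to i % of its maximum), the
total fluorescent intensity

    ∫_0^R I(r) · 2πr dr        (an area-equivalent, in µm²),

the outgrowth area (area enclosed by the outermost perimeter of invading
cells), and the intensity-per-area density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image
from skimage.measure import label as _cc_label

from .images import BinaryMask, DegenerateInputError, ValidationError


@dataclass
class RadialProfile:
    """Normalized foreground fraction per annular bin around a centroid.

    ``radii`` are bin-centre radii in µm (strictly increasing); ``intensity``
    the in-bin foreground fraction (each in [0, 1]); ``pixel_counts`` the
    number of pixels per bin.  Bins that contain no pixels are reported with
    intensity 0 and flagged in ``empty_bins``.
    """

    radii: np.ndarray
    intensity: np.ndarray
    centroid_um: tuple[float, float]
    pixel_counts: np.ndarray
    bin_width_um: float
    empty_bins: np.ndarray = None

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.pixel_counts = np.asarray(self.pixel_counts)
        if self.empty_bins is None:
            self.empty_bins = self.pixel_counts == 0
        if not (len(self.radii) == len(self.intensity) == len(self.pixel_counts)):
            raise ValidationError("profile arrays must share length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValidationError("radii must be strictly increasing")
        if np.any((self.intensity < 0) | (self.intensity > 1 + 1e-12)):
            raise ValidationError("intensity values must lie in [0, 1]")


@dataclass
class InvasionMetrics:
    """Per-image invasion summary.

    ``total_intensity_um2`` is the Eq.-style polar integral of the radial
    profile (equals the foreground area up to discretization);
    ``density`` = total intensity / outgrowth area, a dimensionless occupancy
    of the invaded region.
    """

    r25_um: float
    r50_um: float
    r75_um: float
    outgrowth_area_um2: float
    total_intensity_um2: float
    density: float


def spheroid_centroid(mask: BinaryMask) -> tuple[float, float]:
    """Centroid (y, x) in µm of the largest connected foreground component.

    The largest component is taken to be the spheroid body, so stray
    invading specks do not drag the origin of the radial coordinate.
    """
    if not mask.data.any():
        raise DegenerateInputError("cannot locate a spheroid in an empty mask")
    labels = _cc_label(mask.data, connectivity=mask.ndim)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    body = labels == counts.argmax()
    cy, cx = ndi.center_of_mass(body)
    return (cy * mask.spacing[0], cx * mask.spacing[1])


def radial_profile(
    mask: BinaryMask,
    centroid_um: tuple[float, float],
    bin_width_um: float | None = None,
) -> RadialProfile:
    """Radial distribution of foreground fraction around ``centroid_um``.

    Pixels are assigned to annular bins by Euclidean distance (µm) from the
    centroid; each bin's intensity is foreground pixels / total pixels in
    that bin.  The profile extends only to the largest radius fully
    contained in the image, so no bin is biased by a partially-visible
    annulus.  Default bin width is one pixel.
    """
    if mask.ndim != 2:
        raise ValidationError("radial_profile expects a 2D mask")
    sy, sx = mask.spacing
    if bin_width_um is None:
        bin_width_um = min(sy, sx)
    if bin_width_um <= 0:
        raise ValidationError("bin_width_um must be positive")
    h, w = mask.shape
    cy, cx = centroid_um
    if not (0 <= cy <= (h - 1) * sy and 0 <= cx <= (w - 1) * sx):
        raise ValidationError("centroid lies outside the image bounds")

    yy = np.arange(h)[:, None] * sy - cy
    xx = np.arange(w)[None, :] * sx - cx
    r = np.hypot(yy, xx)
    # largest radius whose full annulus is inside the image
    r_max = min(cy, (h - 1) * sy - cy, cx, (w - 1) * sx - cx)
    n_bins = int(np.floor(r_max / bin_width_um))
    if n_bins < 1:
        raise ValidationError(
            "centroid too close to the border for even one radial bin"
        )
    idx = np.floor(r / bin_width_um).astype(int)
    inside = idx < n_bins
    total = np.bincount(idx[inside], minlength=n_bins)
    fg = np.bincount(idx[inside & mask.data], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(total > 0, fg / np.maximum(total, 1), 0.0)
    radii = (np.arange(n_bins) + 0.5) * bin_width_um
    return RadialProfile(
        radii=radii,
        intensity=intensity,
        centroid_um=(cy, cx),
        pixel_counts=total,
        bin_width_um=bin_width_um,
    )


def _isotonic_nonincreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-squares non-increasing fit by pool-adjacent-violators."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    # fit a non-decreasing sequence to the reversed series, then reverse back
    vals = list(y[::-1])
    wts = list(w[::-1])
    means, weights, counts = [], [], []
    for v, wt in zip(vals, wts):
        means.append(v)
        weights.append(wt)
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), weights.pop(), counts.pop()
            m1, w1, c1 = means.pop(), weights.pop(), counts.pop()
            wtot = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wtot if wtot > 0 else (m1 + m2) / 2)
            weights.append(wtot)
            counts.append(c1 + c2)
    out = np.concatenate([np.full(c, m) for m, c in zip(means, counts)])
    return out[::-1]


def isotonic_envelope(profile: RadialProfile) -> np.ndarray:
    """Non-increasing envelope of the profile (pixel-count weighted).

    Annulus sampling noise makes raw profiles wiggle; the envelope gives
    every threshold a unique, stable crossing radius.  Empty bins get zero
    weight so they cannot pull the fit.
    """
    w = profile.pixel_counts.astype(float)
    return _isotonic_nonincreasing(profile.intensity, w)


def r_metric(profile: RadialProfile, percent: float) -> float:
    """Radius (µm) where the profile falls to ``percent`` % of its maximum.

    A non-increasing isotonic envelope is fitted first; the crossing of
    ``(percent/100) · max`` is then located by linear interpolation between
    bin centres.  If the envelope never falls below the threshold the
    largest profiled radius is returned (flagged via ``np.inf`` comparison
    by callers that care); an all-zero profile is degenerate.
    """
    if not (0 < percent < 100):
        raise ValidationError("percent must lie strictly between 0 and 100")
    if len(profile.radii) < 2:
        raise ValidationError("profile needs at least two bins")
    env = isotonic_envelope(profile)
    peak = env.max()
    if peak <= 0:
        raise DegenerateInputError("all-zero radial profile has no r metrics")
    target = percent / 100.0 * peak
    r, y = profile.radii, env
    below = np.flatnonzero(y < target)
    if below.size == 0:
        return float(r[-1])  # never crossed within the profiled range
    j = below[0]
    if j == 0:
        return float(r[0])
    r0, r1, y0, y1 = r[j - 1], r[j], y[j - 1], y[j]
    if y0 == y1:
        return float(r1)
    return float(r0 + (y0 - target) / (y0 - y1) * (r1 - r0))


def total_intensity(profile: RadialProfile) -> float:
    """Total fluorescent intensity ∫ I(r)·2πr dr (µm²), trapezoid rule.

    For a binarized image this equals the foreground area inside the
    profiled disk, up to discretization of the annuli.
    """
    r, y = profile.radii, profile.intensity
    # extend to r=0 and to the outer bin edge so the integral covers the disk
    r_ext = np.concatenate(([0.0], r, [r[-1] + profile.bin_width_um / 2]))
    y_ext = np.concatenate(([y[0]], y, [y[-1]]))
    return float(np.trapezoid(y_ext * 2 * np.pi * r_ext, r_ext))


def outgrowth_area(mask: BinaryMask, concave: bool = False, closing_um: float = 20.0) -> float:
    """Area (µm²) enclosed by the outermost perimeter of invading cells.

    Default is the convex hull of all foreground pixels (parameter-free and
    reproducible).  ``concave=True`` instead closes the mask with a disk of
    ``closing_um`` and fills holes, tracing a tighter outer contour.
    """
    if not mask.data.any():
        raise DegenerateInputError("outgrowth area undefined for empty mask")
    if mask.ndim != 2:
        raise ValidationError("outgrowth_area expects a 2D mask")
    if concave:
        px = min(mask.spacing)
        r = max(1, int(round(closing_um / px)))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        footprint = (yy**2 + xx**2) <= r**2
        closed = ndi.binary_closing(mask.data, structure=footprint)
        hull = ndi.binary_fill_holes(closed)
    else:
        hull = convex_hull_image(mask.data)
    return float(hull.sum()) * mask.pixel_area_um2


def intensity_density(total_intensity_um2: float, outgrowth_area_um2: float) -> float:
    """Cell-packing density of the invaded region: total intensity / area."""
    if outgrowth_area_um2 <= 0:
        raise DegenerateInputError("outgrowth area must be positive")
    return total_intensity_um2 / outgrowth_area_um2


def invasion_metrics(
    mask: BinaryMask,
    bin_width_um: float | None = None,
    concave: bool = False,
) -> tuple[InvasionMetrics, RadialProfile]:
    """Full invasion summary for one binarized spheroid image."""
    c = spheroid_centroid(mask)
    prof = radial_profile(mask, c, bin_width_um)
    ti = total_intensity(prof)
    area = outgrowth_area(mask, concave=concave)
    return (
        InvasionMetrics(
            r25_um=r_metric(prof, 25),
            r50_um=r_metric(prof, 50),
            r75_um=r_metric(prof, 75),
            outgrowth_area_um2=area,
            total_intensity_um2=ti,
            density=intensity_density(ti, area),
        ),
        prof,
    )
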