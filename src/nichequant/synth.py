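"""Synthetic scenes and assay tables with known ground truth.

No imaging or assay data were deposited with the study this pipeline
re-implements, so every pipeline input is emulated here with planted,
analytically known truth: radially decaying invasion fields around a
spheroid core, rasterized branching tube networks with exact
length/branch/junction counts, cell–vessel scenes with planted per-cell
distances and marker fractions, dose-response tables drawn from a known
GR sigmoid, Ct tables with planted fold changes, and cytokine-array spot
grids with reference spots and per-membrane exposure factors.

Every generator takes an explicit seed and reproduces its artifact
bit-exactly; the returned :class:`SceneTruth` carries everything needed
to compute the expected output of the corresponding pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .images import BinaryMask, LabeledObjects, ValidationError
from .assays import gr_sigmoid, gr50_from_params


@dataclass
class SceneTruth:
    """Planted parameters of one generated artifact."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]


# ---------------------------------------------------------------------------
# Spheroid invasion scenes


def logistic_occupancy(r, r0_um: float, s_um: float):
    """Occupancy probability 1 / (1 + exp((r − R0)/s)) of the invasion field."""
    return 1.0 / (1.0 + np.exp((np.asarray(r, dtype=float) - r0_um) / s_um))


def analytic_r_metric(r0_um: float, s_um: float, percent: float) -> float:
    """Radius where the logistic field equals ``percent`` % of its maximum."""
    return r0_um + s_um * math.log(100.0 / percent - 1.0)


def make_spheroid_scene(
    r0_um: float = 60.0,
    s_um: float = 10.0,
    image_size: int = 256,
    spacing_um: float = 1.0,
    occupancy_noise: bool = True,
    seed: int = 0,
) -> tuple[BinaryMask, SceneTruth]:
    """Spheroid-plus-invasion mask with a logistic radial occupancy field.

    A filled core (radius R0 − 5s, where occupancy exceeds 0.993) sits at
    the image centre; outside it each pixel is foreground with probability
    ``1/(1+exp((r−R0)/s))``.  With ``occupancy_noise=False`` the field is
    thresholded at 0.5 instead, yielding a hard disk of radius R0.

    Truth carries the analytic r25/r50/r75 of the planted field.
    """
    half = (image_size - 1) / 2.0 * spacing_um
    if not r0_um + 5 * s_um < half:
        raise ValidationError(
            "logistic profile truncated by the image border: "
            "require R0 + 5s < half-width"
        )
    rng = np.random.default_rng(seed)
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(yy - c, xx - c) * spacing_um
    p = logistic_occupancy(r, r0_um, s_um)
    if occupancy_noise:
        mask = rng.random(r.shape) < p
        mask |= r <= max(0.0, r0_um - 5 * s_um)
    else:
        mask = p >= 0.5
    truth = SceneTruth(
        kind="spheroid",
        seed=seed,
        params={
            "r0_um": r0_um,
            "s_um": s_um,
            "centroid_um": (c * spacing_um, c * spacing_um),
            "r25_um": analytic_r_metric(r0_um, s_um, 25),
            "r50_um": analytic_r_metric(r0_um, s_um, 50),
            "r75_um": analytic_r_metric(r0_um, s_um, 75),
            "spacing_um": spacing_um,
        },
    )
    return BinaryMask(data=mask, spacing=spacing_um), truth


# ---------------------------------------------------------------------------
# Vessel networks

#: canonical in-plane directions (multiples of 45°) — digital straight
#: lines along these orientations have step-sum lengths equal to their
#: Euclidean length, so planted totals are exact up to discretization.
_CANONICAL = np.arange(8) * (np.pi / 4)


def _segment_points(p0, p1, step=0.25):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


def _seg_min_dist(a0, a1, pts):
    """Min distance from sampled points ``pts`` to segment (a0, a1)."""
    a0, a1 = np.asarray(a0, float), np.asarray(a1, float)
    d = a1 - a0
    L2 = float(d @ d)
    t = np.clip(((pts - a0) @ d) / L2, 0, 1) if L2 > 0 else np.zeros(len(pts))
    proj = a0 + t[:, None] * d
    return float(np.sqrt(((pts - proj) ** 2).sum(axis=1)).min())


def rasterize_tubes(
    segments, shape, spacing, tube_radius_um: float
) -> BinaryMask:
    """Rasterize polyline segments (voxel coords) as tubes of physical
    radius ``tube_radius_um`` (the centerline voxels are always included)."""
    center = np.zeros(shape, dtype=bool)
    for p0, p1 in segments:
        pts = np.round(_segment_points(p0, p1)).astype(int)
        pts = np.clip(pts, 0, np.array(shape) - 1)
        center[tuple(pts.T)] = True
    dist = ndi.distance_transform_edt(~center, sampling=spacing)
    return BinaryMask(data=(dist <= tube_radius_um) | center, spacing=spacing)


def make_vessel_network(
    n_segments: int = 12,
    tube_radius_um: float = 7.5,
    shape: tuple[int, int, int] = (40, 384, 384),
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0),
    seg_len_um: tuple[float, float] = (60.0, 90.0),
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[BinaryMask, SceneTruth]:
    """Random branching tube tree with exact planted morphometry.

    The tree grows by bifurcation (or one trifurcation when parity
    requires) at leaf endpoints, so branch count equals ``n_segments`` and
    junction count equals the number of branching events, both exact by
    construction.  Segments run mostly in-plane along near-canonical
    orientations (±4° jitter) with junction separations well above the
    tube radius, so skeleton measurement recovers the planted totals.

    ``n_segments`` must be 1 or ≥ 3 with ``n_segments − 1`` expressible as
    a sum of 2s and 3s (every integer ≥ 2; n = 2 is rejected because two
    chained segments form a single branch).
    """
    if n_segments < 1 or n_segments == 2:
        raise ValidationError("n_segments must be 1 or ≥ 3")
    rng = np.random.default_rng(seed)
    sz, sy, sx = spacing
    # clearance between non-adjacent tubes: gap well above one
    # tube diameter so thinning never bridges distinct branches
    min_sep_vox = 2.0 * tube_radius_um / min(sy, sx) + 8.0

    def seg_len_vox():
        return rng.uniform(*seg_len_um) / min(sy, sx)

    remaining = n_segments - 1
    events = []
    while remaining > 0:
        k = 3 if remaining % 2 == 1 and remaining >= 3 else 2
        if remaining == 3 and events:
            k = 3
        events.append(k)
        remaining -= k
    if remaining != 0:
        raise ValidationError(f"cannot reach {n_segments} segments by 2/3-way events")

    zmid = float(shape[0] // 2)
    margin = 2 * tube_radius_um / min(sy, sx) + 4

    for _ in range(max_tries):
        segments: list[tuple[np.ndarray, np.ndarray]] = []
        sample_pts: list[np.ndarray] = []

        def in_bounds(p):
            return (
                2 <= p[0] <= shape[0] - 3
                and margin <= p[1] <= shape[1] - 1 - margin
                and margin <= p[2] <= shape[2] - 1 - margin
            )

        def try_add(p0, theta, length):
            # planted segments stay in one z-plane: a z-drifting digital
            # path under coarse z spacing would not have a well-defined
            # step-sum length to plant as truth
            d = np.array([0.0, math.sin(theta), math.cos(theta)])
            p1 = np.round(p0 + d * length)  # snap to the voxel grid:
            # fractional endpoints produce stair patterns that topological
            # thinning handles poorly
            if not in_bounds(p1):
                return None
            pts = _segment_points(p0, p1, step=1.0)
            interior = pts[3:-3] if len(pts) > 8 else pts
            far = pts[min(int(2 * min_sep_vox), len(pts) - 2):]
            for (q0, q1) in segments:
                if any(np.allclose(q, p0) for q in (q0, q1)):
                    # incident segment: check only the far part of the new
                    # one (children always diverge at ≥45°, so near the
                    # shared endpoint proximity is expected)
                    if _seg_min_dist(q0, q1, far) < min_sep_vox:
                        return None
                elif _seg_min_dist(q0, q1, interior) < min_sep_vox:
                    return None
            return p1

        start = np.array([
            zmid,
            float(rng.integers(int(margin) + 10, shape[1] - int(margin) - 10)),
            float(rng.integers(int(margin) + 10, shape[2] - int(margin) - 10)),
        ])
        theta0 = rng.choice(_CANONICAL) + rng.uniform(-0.05, 0.05)
        p1 = try_add(start, theta0, seg_len_vox())
        if p1 is None:
            continue
        segments.append((start, p1))
        leaves = [(p1, theta0)]
        ok = True
        n_junctions = 0
        for k in events:
            placed = False
            for li in rng.permutation(len(leaves)):
                leaf, ltheta = leaves[li]
                # spread k children around the parent direction at ±45°/0°
                signs = (-1.0, 1.0) if k == 2 else (-1.0, 0.0, 1.0)
                n_before = len(segments)
                kids = []
                for sgn in signs:
                    dth = sgn * np.pi / 4 + rng.uniform(-0.05, 0.05)
                    q1 = try_add(leaf, ltheta + dth, seg_len_vox())
                    if q1 is None:
                        kids = None
                        break
                    kids.append((q1, ltheta + dth))
                    segments.append((leaf, q1))
                if kids is None:
                    del segments[n_before:]  # roll back partial children
                    continue
                leaves.pop(int(li))
                leaves.extend(kids)
                n_junctions += 1
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok or len(segments) != n_segments:
            continue

        phys = np.array([sz, sy, sx])
        lengths = [
            float(np.linalg.norm((p1 - p0) * phys)) for p0, p1 in segments
        ]
        mask = rasterize_tubes(segments, shape, spacing, tube_radius_um)
        volume_mm3 = float(np.prod(shape)) * sz * sy * sx / 1e9
        truth = SceneTruth(
            kind="vessel_network",
            seed=seed,
            params={
                "n_branches": n_segments,
                "n_junctions": n_junctions,
                "total_length_um": float(sum(lengths)),
                "segment_lengths_um": lengths,
                "segments_vox": [(p0.tolist(), p1.tolist()) for p0, p1 in segments],
                "tube_radius_um": tube_radius_um,
                "volume_mm3": volume_mm3,
                "total_length_mm_per_mm3": sum(lengths) / 1000.0 / volume_mm3,
                "branches_per_mm3": n_segments / volume_mm3,
                "junctions_per_mm3": n_junctions / volume_mm3,
            },
        )
        return mask, truth
    raise RuntimeError(
        f"could not pack {n_segments} segments after {max_tries} tries"
    )


def make_tube(
    length_um: float = 100.0,
    tube_radius_um: float = 7.5,
    shape=(16, 64, 160),
    spacing=(5.0, 1.0, 1.0),
    angle_deg: float = 0.0,
) -> tuple[BinaryMask, SceneTruth]:
    """Single straight tube, optionally rotated in-plane; exact truth."""
    c = np.array([shape[0] // 2, shape[1] // 2, shape[2] // 2], dtype=float)
    th = math.radians(angle_deg)
    d = np.array([0.0, math.sin(th), math.cos(th)])
    half = length_um / 2.0 / min(spacing[1], spacing[2])
    p0, p1 = c - d * half, c + d * half
    mask = rasterize_tubes([(p0, p1)], shape, spacing, tube_radius_um)
    truth = SceneTruth(
        kind="tube", seed=0,
        params={"total_length_um": length_um, "n_branches": 1,
                "n_junctions": 0, "angle_deg": angle_deg},
    )
    return mask, truth


def make_y_network(
    arm_um: float = 100.0,
    tube_radius_um: float = 7.5,
    shape=(16, 300, 300),
    spacing=(5.0, 1.0, 1.0),
) -> tuple[BinaryMask, SceneTruth]:
    """Three equal arms meeting at one junction (exact planted geometry)."""
    c = np.array([shape[0] // 2, shape[1] // 2, shape[2] // 2], dtype=float)
    segs = []
    for ang in (90.0, 210.0, 330.0):
        th = math.radians(ang)
        d = np.array([0.0, math.sin(th), math.cos(th)])
        segs.append((c, c + d * arm_um / min(spacing[1], spacing[2])))
    mask = rasterize_tubes(segs, shape, spacing, tube_radius_um)
    truth = SceneTruth(
        kind="y", seed=0,
        params={"total_length_um": 3 * arm_um, "n_branches": 3,
                "n_junctions": 1, "n_endpoints": 3},
    )
    return mask, truth


def make_loop(
    side_um: float = 50.0,
    tube_radius_um: float = 7.5,
    shape=(16, 120, 120),
    spacing=(5.0, 1.0, 1.0),
) -> tuple[BinaryMask, SceneTruth]:
    """Closed square loop: no endpoints, no junctions, one cycle branch."""
    z = shape[0] // 2
    s = side_um / min(spacing[1], spacing[2])
    y0, x0 = float((shape[1] - int(s)) // 2), float((shape[2] - int(s)) // 2)
    corners = [
        np.array([z, y0, x0]), np.array([z, y0, x0 + s]),
        np.array([z, y0 + s, x0 + s]), np.array([z, y0 + s, x0]),
    ]
    segs = [(corners[i], corners[(i + 1) % 4]) for i in range(4)]
    mask = rasterize_tubes(segs, shape, spacing, tube_radius_um)
    truth = SceneTruth(
        kind="loop", seed=0,
        params={"total_length_um": 4 * side_um, "n_branches": 1,
                "n_junctions": 0, "n_endpoints": 0},
    )
    return mask, truth


# ---------------------------------------------------------------------------
# Proximity scenes


def make_proximity_scene(
    cell_specs: list[dict],
    shape: tuple[int, int] = (256, 256),
    spacing_um: float = 1.0,
    cell_radius_um: float = 4.0,
    vessel_half_width_px: int = 2,
    seed: int = 0,
) -> tuple[BinaryMask, LabeledObjects, pd.DataFrame, SceneTruth]:
    """Vessel line plus circular tumor cells at planted distances.

    The vessel is a full-height vertical band, so every pixel's distance
    to it is exactly its horizontal offset — circular cells centred at
    horizontal offset *d* therefore have mean pixel distance exactly *d*
    (their pixel offsets are symmetric about the centre).  Each spec dict
    gives ``distance_um`` plus optional boolean marker flags.

    Returns (vessel mask, cell objects, marker table, truth); truth rows
    align with the returned objects' labels.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    x_v = vessel_half_width_px  # right edge column of the vessel band
    vessel = np.zeros(shape, dtype=bool)
    vessel[:, : x_v + 1] = True

    r_px = int(round(cell_radius_um / spacing_um))
    yy, xx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    disk = (yy**2 + xx**2) <= r_px**2

    cells = np.zeros(shape, dtype=np.int32)
    gap = 2 * r_px + 4
    y_slots = list(range(r_px + 2, h - r_px - 2, gap))
    if len(y_slots) < len(cell_specs):
        raise ValidationError(
            f"cannot place {len(cell_specs)} cells in a {h}-row field"
        )
    rng.shuffle(y_slots)
    rows = []
    for i, spec in enumerate(cell_specs):
        d = float(spec["distance_um"])
        cx = x_v + int(round(d / spacing_um))
        if cx + r_px >= w:
            raise ValidationError(
                f"cell {i} at {d} µm does not fit in a {w}-column field"
            )
        cy = y_slots[i]
        cells[cy - r_px : cy + r_px + 1, cx - r_px : cx + r_px + 1][disk] = i + 1
        row = {"planted_label": i + 1, "distance_um": d}
        row.update({k: bool(v) for k, v in spec.items() if k != "distance_um"})
        rows.append(row)
    truth_df = pd.DataFrame(rows)
    labeled = LabeledObjects(labels=cells, spacing=(spacing_um, spacing_um))
    # map generator labels to scan-order labels via centroids
    markers = truth_df.rename(columns={"planted_label": "label"}).drop(
        columns=["distance_um"]
    )
    truth = SceneTruth(
        kind="proximity", seed=seed,
        params={"cells": truth_df, "vessel_edge_col": x_v,
                "cell_radius_um": cell_radius_um},
    )
    return (
        BinaryMask(data=vessel, spacing=spacing_um),
        labeled,
        markers,
        truth,
    )


# ---------------------------------------------------------------------------
# Marker overlap scenes


def make_marker_scene(
    n_cells: int = 50,
    positive_fraction: float = 0.6,
    overlap_high: float = 0.35,
    overlap_low: float = 0.25,
    cell_w: int = 20,
    cell_h: int = 10,
    seed: int = 0,
) -> tuple[LabeledObjects, LabeledObjects, SceneTruth]:
    """GBM and marker label images with exactly controlled overlap fractions.

    Cells are ``cell_h × cell_w`` rectangles on a padded grid; each
    planted positive receives a same-size marker rectangle shifted so that
    exactly ``overlap_high`` of the *marker* area lies on the cell, each
    planted negative a marker at ``overlap_low`` (or none when 0).  Shifts
    are integer-exact, so recovered positive fractions are exact.
    """
    if not (0 <= overlap_low < 0.3 <= overlap_high <= 1):
        raise ValidationError("require overlap_low < 0.3 ≤ overlap_high")
    dx_hi = int(round((1 - overlap_high) * cell_w))
    dx_lo = int(round((1 - overlap_low) * cell_w))
    if abs(dx_hi / cell_w - (1 - overlap_high)) > 1e-9 or (
        overlap_low > 0 and abs(dx_lo / cell_w - (1 - overlap_low)) > 1e-9
    ):
        raise ValidationError(
            "overlap fractions must be integer-exact for the given cell width"
        )
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_cells * positive_fraction))
    flags = np.zeros(n_cells, dtype=bool)
    flags[:n_pos] = True
    rng.shuffle(flags)

    pad_x, pad_y = 2 * cell_w + 6, 6
    per_row = max(1, int(np.ceil(np.sqrt(n_cells))))
    W = per_row * (cell_w + pad_x) + pad_x
    H = int(np.ceil(n_cells / per_row)) * (cell_h + pad_y) + pad_y
    gbm = np.zeros((H, W), dtype=np.int32)
    mrk = np.zeros((H, W), dtype=np.int32)
    m_id = 0
    for i in range(n_cells):
        ry, rx = divmod(i, per_row)
        y0 = pad_y + ry * (cell_h + pad_y)
        x0 = pad_x + rx * (cell_w + pad_x)
        gbm[y0 : y0 + cell_h, x0 : x0 + cell_w] = i + 1
        dx = dx_hi if flags[i] else (dx_lo if overlap_low > 0 else None)
        if dx is not None:
            m_id += 1
            mrk[y0 : y0 + cell_h, x0 + dx : x0 + dx + cell_w] = m_id
    truth = SceneTruth(
        kind="marker_scene", seed=seed,
        params={
            "positive": flags,
            "positive_fraction": n_pos / n_cells,
            "overlap_high": dx_hi and (cell_w - dx_hi) / cell_w or 1.0,
            "overlap_low": overlap_low and (cell_w - dx_lo) / cell_w or 0.0,
        },
    )
    return (
        LabeledObjects(labels=gbm, spacing=(1.0, 1.0)),
        LabeledObjects(labels=mrk, spacing=(1.0, 1.0)),
        truth,
    )


# ---------------------------------------------------------------------------
# Dose-response tables


def make_dose_response(
    gr_inf: float = -0.2,
    gec50_uM: float = 300.0,
    h: float = 2.0,
    x0: float = 1000.0,
    growth_doublings: float = 2.0,
    concentrations_uM=(0.0, 18.75, 37.5, 75.0, 150.0, 300.0, 600.0),
    noise_cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SceneTruth]:
    """Tidy viability table drawn from a planted GR sigmoid.

    The control grows ``growth_doublings`` doublings over the treatment
    window (x_ctrl = x0·2^doublings); treated signals are inverted from
    the GR curve, x(c) = x0·2^{log2(GR(c)+1)·log2(x_ctrl/x0)}, then
    multiplied by lognormal noise of the stated CV.  Truth holds the
    analytic GR50.
    """
    if growth_doublings <= 0:
        raise ValidationError("growth_doublings must be positive")
    conc = np.asarray(concentrations_uM, dtype=float)
    rng = np.random.default_rng(seed)
    x_ctrl = x0 * 2.0**growth_doublings
    gr = gr_sigmoid(conc, gr_inf, gec50_uM, h)
    x_c = x0 * 2.0 ** (np.log2(gr + 1.0) * np.log2(x_ctrl / x0))
    if np.any(x_c <= 0):
        raise ValidationError("planted parameters yield nonpositive signals")
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(v, n):
        if sigma == 0:
            return np.full(n, v)
        return v * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n)

    rows = []
    for rep, v in enumerate(noisy(x0, n_reps)):
        rows.append({"sample": f"start_{rep}", "concentration_uM": 0.0,
                     "signal": v, "timepoint": "start", "role": "untreated",
                     "replicate": rep})
    for rep, v in enumerate(noisy(x_ctrl, n_reps)):
        rows.append({"sample": f"ctrl_{rep}", "concentration_uM": 0.0,
                     "signal": v, "timepoint": "end", "role": "control",
                     "replicate": rep})
    for ci, cval in enumerate(conc):
        for rep, v in enumerate(noisy(x_c[ci], n_reps)):
            rows.append({"sample": f"c{ci}_{rep}", "concentration_uM": cval,
                         "signal": v, "timepoint": "end", "role": "treated",
                         "replicate": rep})
    table = pd.DataFrame(rows)
    truth = SceneTruth(
        kind="dose_response", seed=seed,
        params={"gr_inf": gr_inf, "gec50_uM": gec50_uM, "h": h,
                "gr50_uM": gr50_from_params(gr_inf, gec50_uM, h),
                "x0": x0, "x_ctrl": x_ctrl, "gr_true": gr, "noise_cv": noise_cv},
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def make_ct_table(
    planted_folds: dict,
    reference_gene: str = "CD31",
    baseline: tuple[str, object] = ("EC", 0),
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    n_reps: int = 3,
    noise_sd: float = 0.0,
    sample_shift_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SceneTruth]:
    """Ct table with planted per-(gene, group, day) fold changes.

    ``planted_folds`` maps gene → {(group, day): fold}.  Target Cts are
    built as ``base_ct − log2(fold) + shift + noise`` and the reference
    gene as ``reference_ct + shift + noise``, where ``shift`` is a shared
    per-sample loading offset the ΔΔCT method must cancel.  The baseline
    condition is added automatically with fold 1.
    """
    rng = np.random.default_rng(seed)
    conditions = {baseline}
    for folds in planted_folds.values():
        conditions.update(folds)
    rows = []
    for group, day in sorted(conditions, key=str):
        for rep in range(n_reps):
            sample = f"{group}_d{day}_{rep}"
            shift = rng.normal(0, sample_shift_sd)
            rows.append({"sample": sample, "group": group, "day": day,
                         "gene": reference_gene,
                         "ct": reference_ct + shift + rng.normal(0, noise_sd)})
            for gene, folds in planted_folds.items():
                # every gene is assayed in every sample; unspecified
                # conditions default to no change
                fold = folds.get((group, day), 1.0)
                if fold <= 0:
                    raise ValidationError("planted fold changes must be positive")
                rows.append({"sample": sample, "group": group, "day": day,
                             "gene": gene,
                             "ct": base_ct - math.log2(fold) + shift
                             + rng.normal(0, noise_sd)})
    truth = SceneTruth(
        kind="ct_table", seed=seed,
        params={"planted_folds": planted_folds, "baseline": baseline,
                "reference_gene": reference_gene},
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Cytokine spot arrays


def make_spot_array(
    analyte_values: dict,
    group_membranes: dict,
    reference_level: float = 1000.0,
    exposure_factors: dict | None = None,
    n_reference: int = 3,
    n_dup: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SceneTruth]:
    """Spot-intensity tables for a set of membranes with planted ratios.

    ``analyte_values`` maps analyte → {group: value}; a membrane of group
    *g* carries duplicate spots of intensity ``value · reference_level ·
    exposure`` plus ``n_reference`` positive reference spots at
    ``reference_level · exposure``.  Reference-spot normalization must
    cancel the exposure factor exactly, recovering ``value``.

    Returns (spots, spot_map, truth).
    """
    rng = np.random.default_rng(seed)
    if exposure_factors is None:
        exposure_factors = {
            m: float(rng.uniform(0.5, 2.0)) for m in group_membranes
        }
    spot_rows, map_rows = [], []
    map_done = False
    for membrane, group in group_membranes.items():
        exp = exposure_factors[membrane]
        sid = 0
        for _ in range(n_reference):
            sid += 1
            spot_rows.append({"membrane": membrane, "spot": f"s{sid}",
                              "intensity": reference_level * exp})
            if not map_done:
                map_rows.append({"spot": f"s{sid}", "analyte": "__reference__"})
        for analyte, values in analyte_values.items():
            if values.get(group, 0) <= 0:
                raise ValidationError("planted analyte values must be positive")
            for _ in range(n_dup):
                sid += 1
                spot_rows.append({
                    "membrane": membrane, "spot": f"s{sid}",
                    "intensity": values[group] * reference_level * exp,
                })
                if not map_done:
                    map_rows.append({"spot": f"s{sid}", "analyte": analyte})
        map_done = True
    truth = SceneTruth(
        kind="spot_array", seed=seed,
        params={"analyte_values": analyte_values,
                "exposure_factors": exposure_factors},
    )
    return pd.DataFrame(spot_rows), pd.DataFrame(map_rows), truth
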