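"""Tumor-cell / vasculature proximity analysis.

On a maximum-intensity projection of the vessel channel, an exact
Euclidean distance transform assigns every background pixel its physical
distance to the nearest vessel pixel.  Each tumor-cell object then gets a
scalar distance (mean of the transform over its pixels by default), is
binned into the canonical 10-µm distance bins (0–10, 10–20, …, >50 µm),
and cells closer than 50 µm are counted as residing in the perivascular
niche (PVN).  Marker-positive and -negative subpopulations can be compared
via paired histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .images import (
    BinaryMask,
    DegenerateInputError,
    LabeledObjects,
    ValidationError,
)

#: Left-closed, right-open distance bin edges in µm.  A cell at exactly
#: 50 µm falls in the last bin and is *outside* the PVN.
BIN_EDGES_UM = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf)
BIN_LABELS = ("[0,10)", "[10,20)", "[20,30)", "[30,40)", "[40,50)", "[50,inf)")
PVN_CUTOFF_UM = 50.0


@dataclass
class DistanceMap:
    """Per-pixel µm distance to the nearest vessel pixel (0 on vessels)."""

    data: np.ndarray
    spacing: tuple[float, ...]


@dataclass
class ProximityHistogram:
    """Fractions of cells per distance bin plus the PVN-resident fraction."""

    fractions: np.ndarray
    n_cells: int
    pvn_fraction: float
    bin_labels: tuple[str, ...] = BIN_LABELS

    @property
    def empty(self) -> bool:
        return self.n_cells == 0


def distance_map(vessel_mask: BinaryMask) -> DistanceMap:
    """Exact Euclidean distance transform of the vessel background, µm.

    Uses per-axis physical sampling, so anisotropic pixels are handled
    correctly; works on 2D projections (default) and 3D stacks alike.
    """
    if not vessel_mask.data.any():
        raise DegenerateInputError(
            "vessel mask is empty: distances are undefined"
        )
    dist = ndi.distance_transform_edt(
        ~vessel_mask.data, sampling=vessel_mask.spacing
    )
    return DistanceMap(data=dist, spacing=vessel_mask.spacing)


def assign_bin(distance_um: float) -> str:
    idx = int(np.searchsorted(BIN_EDGES_UM, distance_um, side="right")) - 1
    return BIN_LABELS[min(idx, len(BIN_LABELS) - 1)]


def cell_distances(
    cells: LabeledObjects,
    dmap: DistanceMap,
    aggregation: str = "mean",
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell distance records.

    ``aggregation`` chooses the per-cell scalar: ``"mean"`` (default) of
    the distance transform over the cell's pixels, ``"min"``, or
    ``"centroid"`` (transform value at the rounded centroid pixel).
    Cells touching the image border are flagged (their true nearest vessel
    may lie outside the field) but included.

    ``markers`` may supply boolean columns keyed by ``label`` which are
    joined onto the output.
    """
    if cells.labels.shape != dmap.data.shape:
        raise ValidationError("cells and distance map shapes differ")
    if tuple(cells.spacing) != tuple(dmap.spacing):
        raise ValidationError("cells and distance map spacing differ")
    if aggregation not in ("mean", "min", "centroid"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")

    table = cells.table.copy()
    if table.empty:
        raise DegenerateInputError("no cell objects to measure")
    ids = table["label"].to_numpy()
    if aggregation == "mean":
        vals = ndi.mean(dmap.data, labels=cells.labels, index=ids)
    elif aggregation == "min":
        vals = ndi.minimum(dmap.data, labels=cells.labels, index=ids)
    else:
        axes = [c for c in ("centroid_z_um", "centroid_y_um", "centroid_x_um")
                if c in table.columns]
        idx = tuple(
            np.clip(
                np.round(table[a].to_numpy() / s).astype(int), 0, n - 1
            )
            for a, s, n in zip(axes, cells.spacing, cells.labels.shape)
        )
        vals = dmap.data[idx]

    # border flag: does the object touch any image edge?
    border = np.zeros_like(cells.labels, dtype=bool)
    for ax in range(cells.labels.ndim):
        sl = [slice(None)] * cells.labels.ndim
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    border_ids = set(np.unique(cells.labels[border])) - {0}

    table["distance_um"] = np.asarray(vals, dtype=float)
    table["bin"] = [assign_bin(d) for d in table["distance_um"]]
    table["on_border"] = [int(l) in border_ids for l in ids]
    if markers is not None:
        table = table.merge(markers, on="label", how="left")
    return table


def bin_distances(records: pd.DataFrame) -> ProximityHistogram:
    """Histogram of cell fractions over the canonical distance bins."""
    if records.empty:
        raise DegenerateInputError("no cell records to bin")
    d = records["distance_um"].to_numpy(dtype=float)
    counts, _ = np.histogram(d, bins=BIN_EDGES_UM)
    n = len(d)
    fractions = counts / n
    pvn = float(fractions[:-1].sum())
    return ProximityHistogram(fractions=fractions, n_cells=n, pvn_fraction=pvn)


def split_by_marker(
    records: pd.DataFrame, marker: str
) -> tuple[ProximityHistogram, ProximityHistogram]:
    """Paired histograms for the marker− and marker+ subpopulations.

    The two histograms partition the cells: every record lands in exactly
    one.  An empty subpopulation is returned as an empty histogram
    (``n_cells == 0``, all-zero fractions) rather than an error, so paired
    comparisons degrade gracefully.
    """
    if marker not in records.columns:
        raise ValidationError(f"marker {marker!r} not present in records")
    calls = records[marker].astype(bool)

    def _hist(sub: pd.DataFrame) -> ProximityHistogram:
        if sub.empty:
            return ProximityHistogram(
                fractions=np.zeros(len(BIN_LABELS)), n_cells=0,
                pvn_fraction=float("nan"),
            )
        return bin_distances(sub)

    return _hist(records[~calls]), _hist(records[calls])


def histogram_table(
    hists: dict[str, ProximityHistogram]
) -> pd.DataFrame:
    """Long-format table (population, bin, fraction, n_cells, pvn_fraction)."""
    rows = []
    for name, h in hists.items():
        for lbl, frac in zip(h.bin_labels, h.fractions):
            rows.append(
                {
                    "population": name,
                    "bin": lbl,
                    "fraction": frac,
                    "n_cells": h.n_cells,
                    "pvn_fraction": h.pvn_fraction,
                }
            )
    return pd.DataFrame(rows)
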