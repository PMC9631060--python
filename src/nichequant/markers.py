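"""Marker-positivity calls and population fractions.

A tumor cell is called positive for a nuclear/functional marker (SOX2,
KI67, EdU, cPARP) when some object segmented from the marker channel
shares at least a threshold fraction of its area with that cell — 30 % by
default.  The overlap denominator is the marker object's area; the
GBM-cell-area denominator is available behind a flag.  Population
fractions and the composite ratios used to summarise proliferation,
apoptosis and treatment response are computed from the calls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .images import DegenerateInputError, LabeledObjects, ValidationError

DEFAULT_MIN_OVERLAP = 0.30


def _pair_counts(gbm_labels: np.ndarray, marker_labels: np.ndarray):
    """Joint pixel counts for every (gbm object, marker object) pair."""
    both = (gbm_labels > 0) & (marker_labels > 0)
    g = gbm_labels[both].ravel()
    m = marker_labels[both].ravel()
    if g.size == 0:
        return {}
    pairs, counts = np.unique(np.stack([g, m]), axis=1, return_counts=True)
    return {
        (int(gi), int(mi)): int(c)
        for gi, mi, c in zip(pairs[0], pairs[1], counts)
    }


def classify_positive(
    gbm: LabeledObjects,
    marker: LabeledObjects,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    denominator: str = "marker",
) -> pd.DataFrame:
    """Per-cell positivity calls by the area-overlap rule.

    For each marker object *m* and GBM cell *g* the overlap fraction is
    |m ∩ g| / |m| (or / |g| with ``denominator="gbm"``).  A cell is
    positive if any marker object reaches ``min_overlap`` with it; a
    marker object straddling two cells can make both positive.  Returns
    the GBM table extended with ``positive`` and ``best_overlap_fraction``
    columns.
    """
    if gbm.labels.shape != marker.labels.shape:
        raise ValidationError("GBM and marker label grids differ in shape")
    if not (0 < min_overlap <= 1):
        raise ValidationError("min_overlap must lie in (0, 1]")
    if denominator not in ("marker", "gbm"):
        raise ValidationError("denominator must be 'marker' or 'gbm'")

    pair = _pair_counts(gbm.labels, marker.labels)
    marker_area = np.bincount(marker.labels.ravel())
    gbm_area = np.bincount(gbm.labels.ravel())

    best = {int(l): 0.0 for l in gbm.table["label"]}
    for (g, m), c in pair.items():
        denom = marker_area[m] if denominator == "marker" else gbm_area[g]
        frac = c / denom
        if frac > best[g]:
            best[g] = frac

    out = gbm.table.copy()
    out["best_overlap_fraction"] = [best[int(l)] for l in out["label"]]
    out["positive"] = out["best_overlap_fraction"] >= min_overlap
    return out


def positive_fraction(calls: pd.DataFrame) -> float:
    """Fraction of GBM cells called positive."""
    if calls.empty:
        raise DegenerateInputError("no GBM cells: positive fraction undefined")
    return float(calls["positive"].mean())


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, ratio reported missing")
        return float("nan")
    if num < 0 or den < 0:
        raise ValidationError(f"{what}: fractions must be nonnegative")
    return num / den


def edu_over_ki67(frac_edu: float, frac_ki67: float) -> float:
    """S-phase fraction normalised to the cycling fraction (EdU+/KI67+)."""
    return _safe_ratio(frac_edu, frac_ki67, "edu_over_ki67")


def treatment_ratio(frac_treated: float, frac_control: float) -> float:
    """Marker fraction in drug-treated over vehicle-control samples
    (e.g. cPARP+ TMZ+/TMZ−)."""
    return _safe_ratio(frac_treated, frac_control, "treatment_ratio")


def apoptosis_proliferation_ratio(frac_cparp: float, frac_ki67: float) -> float:
    """Apoptosis-to-proliferation composite, cPARP+/KI67+."""
    return _safe_ratio(frac_cparp, frac_ki67, "apoptosis_proliferation_ratio")


def fraction_summary(
    call_tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """One-row summary of an image's marker fractions and derived ratios.

    ``call_tables`` maps marker name → classify_positive output for the
    same GBM population.  Ratios are filled in where their inputs exist.
    """
    if not call_tables:
        raise DegenerateInputError("no marker call tables supplied")
    row: dict[str, float] = {}
    n = None
    for name, table in call_tables.items():
        if n is None:
            n = len(table)
        row[f"fraction_{name.lower()}"] = positive_fraction(table)
    row["n_gbm_cells"] = n
    f = row
    if "fraction_edu" in f and "fraction_ki67" in f:
        row["edu_over_ki67"] = edu_over_ki67(f["fraction_edu"], f["fraction_ki67"])
    if "fraction_cparp" in f and "fraction_ki67" in f:
        row["cparp_over_ki67"] = apoptosis_proliferation_ratio(
            f["fraction_cparp"], f["fraction_ki67"]
        )
    return pd.DataFrame([row])
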