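"""Config-driven orchestration of the four analyses.

Each runner takes explicit inputs and an output directory, writes the
stage CSVs plus a machine-readable ``summary.json``, and logs at stage
granularity.  ``run_analysis`` dispatches on a validated config mapping
(YAML-friendly): identical config + inputs produce byte-identical CSV
outputs, and every summary records the package version and a hash of the
config that produced it.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .images import (
    BinaryMask,
    ImageStack,
    ValidationError,
    binarize,
    label_objects,
    max_project,
    read_stack,
    write_stack,
)
from .invasion import invasion_metrics
from .proximity import bin_distances, cell_distances, distance_map, histogram_table, split_by_marker
from .markers import classify_positive, fraction_summary
from .vessels import analyze_vessel_stack
from .assays import ddct_fold_change, gr_from_table, normalize_spots, secretome_fold_change

log = logging.getLogger("nichequant")

_FLOAT_FMT = "%.10g"  # fixed CSV float format → byte-identical reruns


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    log.info("wrote %s (%d rows)", path, len(df))


def _write_summary(out_dir: Path, analysis: str, config: dict, payload: dict) -> None:
    summary = {
        "analysis": analysis,
        "package_version": __version__,
        "config_hash": config_hash(config),
        **payload,
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )


def _load_mask(path, spacing, threshold="otsu") -> BinaryMask:
    stack = read_stack(path, spacing)
    if stack.data.dtype == bool or set(np.unique(stack.data)) <= {0, 1, 255}:
        return BinaryMask(data=stack.data > 0, spacing=stack.spacing)
    if threshold == "otsu":
        return binarize(stack, method="otsu")
    return binarize(stack, method="fixed", threshold=float(threshold))


# ---------------------------------------------------------------------------
# Stage runners


def run_invasion(
    image_paths,
    spacing_um: float,
    out_dir,
    threshold="otsu",
    bin_width_um=None,
    concave_outline: bool = False,
) -> pd.DataFrame:
    """Invasion profiling over a set of (time-lapse) frames.

    Writes one radial-profile CSV per image and a combined metrics CSV;
    returns the metrics table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in image_paths:
        mask = _load_mask(path, spacing_um, threshold)
        metrics, prof = invasion_metrics(
            mask, bin_width_um=bin_width_um, concave=concave_outline
        )
        stem = Path(path).stem
        _write_csv(
            pd.DataFrame(
                {
                    "radius_um": prof.radii,
                    "intensity": prof.intensity,
                    "pixel_count": prof.pixel_counts,
                }
            ),
            out_dir / f"profile_{stem}.csv",
        )
        rows.append(
            {
                "sample": stem,
                "r25_um": metrics.r25_um,
                "r50_um": metrics.r50_um,
                "r75_um": metrics.r75_um,
                "outgrowth_area_um2": metrics.outgrowth_area_um2,
                "total_intensity_um2": metrics.total_intensity_um2,
                "density": metrics.density,
            }
        )
    table = pd.DataFrame(rows)
    _write_csv(table, out_dir / "invasion_metrics.csv")
    return table


def run_vessels(
    stack_path,
    spacing_um,
    out_dir,
    threshold="otsu",
    prune_um: float = 10.0,
) -> pd.DataFrame:
    """Vessel morphometry for one z-stack; writes skeleton TIFF, edge list
    and metrics CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask = _load_mask(stack_path, spacing_um, threshold)
    metrics, graph, skel = analyze_vessel_stack(mask, prune_um=prune_um)
    write_stack(out_dir / "skeleton.tif", skel)
    _write_csv(graph.edge_table(), out_dir / "edges.csv")
    table = pd.DataFrame(
        [
            {
                "sample": Path(stack_path).stem,
                "total_length_mm_per_mm3": metrics.total_length_mm_per_mm3,
                "branches_per_mm3": metrics.branches_per_mm3,
                "junctions_per_mm3": metrics.junctions_per_mm3,
                "avg_branch_length_um": metrics.avg_branch_length_um,
                "analyzed_volume_mm3": metrics.analyzed_volume_mm3,
            }
        ]
    )
    _write_csv(table, out_dir / "vessel_metrics.csv")
    return table


def run_proximity(
    vessel_path,
    cells_path,
    out_dir,
    spacing_um: float = 1.0,
    markers_csv=None,
    aggregation: str = "mean",
    vessel_threshold="otsu",
) -> pd.DataFrame:
    """Proximity mapping: per-cell distances, bins, and histograms
    (overall plus marker+/− splits for every marker column supplied)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vessel_stack = read_stack(vessel_path, spacing_um)
    if vessel_stack.ndim == 3:
        vessel_stack = max_project(vessel_stack)
    vessel = _load_mask_from_stack(vessel_stack, vessel_threshold)
    cells_stack = read_stack(cells_path, spacing_um)
    if cells_stack.ndim == 3:
        cells_stack = max_project(cells_stack)
    from .images import LabeledObjects

    cells = LabeledObjects(
        labels=cells_stack.data.astype(np.int64), spacing=cells_stack.spacing
    )
    markers = pd.read_csv(markers_csv) if markers_csv else None
    dmap = distance_map(vessel)
    records = cell_distances(cells, dmap, aggregation=aggregation, markers=markers)
    _write_csv(records, out_dir / "cell_distances.csv")
    hists = {"all": bin_distances(records)}
    if markers is not None:
        for m in [c for c in markers.columns if c != "label"]:
            neg, pos = split_by_marker(records, m)
            hists[f"{m}-"] = neg
            hists[f"{m}+"] = pos
    _write_csv(histogram_table(hists), out_dir / "proximity_histograms.csv")
    return records


def _load_mask_from_stack(stack: ImageStack, threshold) -> BinaryMask:
    if set(np.unique(stack.data)) <= {0, 1, 255}:
        return BinaryMask(data=stack.data > 0, spacing=stack.spacing)
    if threshold == "otsu":
        return binarize(stack, method="otsu")
    return binarize(stack, method="fixed", threshold=float(threshold))


def run_markers(
    gbm_path,
    marker_paths: dict,
    out_dir,
    spacing_um: float = 1.0,
    min_overlap: float = 0.30,
    min_area_um2: float = 0.0,
) -> pd.DataFrame:
    """Marker-positivity quantification for one image set.

    ``marker_paths`` maps marker name → label/mask TIFF.  Writes per-cell
    calls per marker and a one-row fraction summary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gbm = _load_labels(gbm_path, spacing_um, min_area_um2)
    tables = {}
    for name, path in marker_paths.items():
        marker = _load_labels(path, spacing_um, min_area_um2)
        calls = classify_positive(gbm, marker, min_overlap=min_overlap)
        _write_csv(calls, out_dir / f"calls_{name}.csv")
        tables[name] = calls
    summary = fraction_summary(tables)
    _write_csv(summary, out_dir / "fraction_summary.csv")
    return summary


def _load_labels(path, spacing_um, min_area_um2):
    stack = read_stack(path, spacing_um)
    data = stack.data
    if data.max() <= 1 or set(np.unique(data)) <= {0, 255}:
        mask = BinaryMask(data=data > 0, spacing=stack.spacing)
        return label_objects(mask, min_area_um2=min_area_um2)
    from .images import LabeledObjects

    return LabeledObjects(labels=data.astype(np.int64), spacing=stack.spacing)


def run_gr(table_csv, out_dir) -> pd.DataFrame:
    """GR dose-response quantification from a tidy viability CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(table_csv)
    curve = gr_from_table(table)
    _write_csv(
        pd.DataFrame(
            {"concentration_uM": curve.concentrations_uM, "gr": curve.gr}
        ),
        out_dir / "gr_values.csv",
    )
    params = pd.DataFrame(
        [
            {
                "gr_inf": curve.gr_inf,
                "gec50_uM": curve.gec50_uM,
                "hill": curve.hill,
                "gr50_uM": curve.gr50_uM,
                "ic50_rel_uM": curve.ic50_rel_uM,
                "residual_rms": curve.residual_rms,
            }
        ]
    )
    _write_csv(params, out_dir / "gr_fit.csv")
    return params


def run_pcr(
    table_csv, out_dir, reference_gene="CD31", baseline_group="EC",
    baseline_day=0,
) -> pd.DataFrame:
    """ΔΔCT fold changes for every non-reference gene in the table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(table_csv)
    genes = sorted(set(table["gene"]) - {reference_gene})
    results = pd.concat(
        [
            ddct_fold_change(
                table, g, reference_gene=reference_gene,
                baseline=(baseline_group, baseline_day),
            )
            for g in genes
        ],
        ignore_index=True,
    )
    _write_csv(results, out_dir / "fold_changes.csv")
    return results


def run_secretome(
    spots_csv, map_csv, groups_csv, out_dir, baseline_group="GBM"
) -> pd.DataFrame:
    """Cytokine-array normalization and group fold changes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    normalized = normalize_spots(pd.read_csv(spots_csv), pd.read_csv(map_csv))
    _write_csv(normalized, out_dir / "normalized_spots.csv")
    fc = secretome_fold_change(
        normalized, pd.read_csv(groups_csv), baseline_group=baseline_group
    )
    _write_csv(fc, out_dir / "secretome_fold_changes.csv")
    return fc


# ---------------------------------------------------------------------------
# Config-driven entry point

_SCHEMAS = {
    "invasion": {"images", "spacing_um", "threshold", "bin_width_um",
                 "concave_outline"},
    "vessels": {"stack", "spacing_um", "threshold", "prune_um"},
    "proximity": {"vessel", "cells", "markers_csv", "spacing_um",
                  "aggregation", "vessel_threshold"},
    "markers": {"gbm", "markers", "spacing_um", "min_overlap", "min_area_um2"},
    "gr": {"table"},
    "pcr": {"table", "reference_gene", "baseline_group", "baseline_day"},
    "secretome": {"spots", "map", "groups", "baseline_group"},
}
_REQUIRED = {
    "invasion": {"images", "spacing_um"},
    "vessels": {"stack", "spacing_um"},
    "proximity": {"vessel", "cells"},
    "markers": {"gbm", "markers"},
    "gr": {"table"},
    "pcr": {"table"},
    "secretome": {"spots", "map", "groups"},
}


def validate_config(config: dict) -> dict:
    """Fail-fast config validation: known analysis, no unknown keys,
    required keys present, referenced paths existing."""
    if "analysis" not in config or "out_dir" not in config:
        raise ValidationError("config needs 'analysis' and 'out_dir'")
    analysis = config["analysis"]
    if analysis not in _SCHEMAS:
        raise ValidationError(f"unknown analysis {analysis!r}")
    opts = {k: v for k, v in config.items()
            if k not in ("analysis", "out_dir", "seed", "schema_version")}
    unknown = set(opts) - _SCHEMAS[analysis]
    if unknown:
        raise ValidationError(f"unknown config keys for {analysis}: {sorted(unknown)}")
    missing = _REQUIRED[analysis] - set(opts)
    if missing:
        raise ValidationError(f"missing config keys for {analysis}: {sorted(missing)}")
    return config


def run_analysis(config: dict) -> pd.DataFrame:
    """Execute one analysis from a validated config mapping.

    Writes all stage outputs plus ``summary.json`` and ``run.log`` under
    ``config['out_dir']``; returns the headline result table.
    """
    config = validate_config(config)
    analysis = config["analysis"]
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("analysis=%s config_hash=%s version=%s",
             analysis, config_hash(config), __version__)
    try:
        if analysis == "invasion":
            paths = config["images"]
            if isinstance(paths, str):
                paths = sorted(_glob.glob(paths))
            if not paths:
                raise ValidationError("invasion: image glob matched no files")
            result = run_invasion(
                paths, config["spacing_um"], out_dir,
                threshold=config.get("threshold", "otsu"),
                bin_width_um=config.get("bin_width_um"),
                concave_outline=config.get("concave_outline", False),
            )
        elif analysis == "vessels":
            result = run_vessels(
                config["stack"], config["spacing_um"], out_dir,
                threshold=config.get("threshold", "otsu"),
                prune_um=config.get("prune_um", 10.0),
            )
        elif analysis == "proximity":
            result = run_proximity(
                config["vessel"], config["cells"], out_dir,
                spacing_um=config.get("spacing_um", 1.0),
                markers_csv=config.get("markers_csv"),
                aggregation=config.get("aggregation", "mean"),
                vessel_threshold=config.get("vessel_threshold", "otsu"),
            )
        elif analysis == "markers":
            result = run_markers(
                config["gbm"], config["markers"], out_dir,
                spacing_um=config.get("spacing_um", 1.0),
                min_overlap=config.get("min_overlap", 0.30),
                min_area_um2=config.get("min_area_um2", 0.0),
            )
        elif analysis == "gr":
            result = run_gr(config["table"], out_dir)
        elif analysis == "pcr":
            result = run_pcr(
                config["table"], out_dir,
                reference_gene=config.get("reference_gene", "CD31"),
                baseline_group=config.get("baseline_group", "EC"),
                baseline_day=config.get("baseline_day", 0),
            )
        else:
            result = run_secretome(
                config["spots"], config["map"], config["groups"], out_dir,
                baseline_group=config.get("baseline_group", "GBM"),
            )
    except Exception as exc:
        log.error("stage %s failed: %s", analysis, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    _write_summary(out_dir, analysis, config,
                   {"n_rows": len(result), "columns": list(result.columns)})
    return result


def compare_groups(bundles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tidy long-format table (sample, group, metric, value) from per-group
    metric tables, ready for external statistical software.

    ``bundles`` maps group name → metrics table (as written by a runner).
    All tables must share their numeric metric columns.
    """
    if len(bundles) < 2:
        raise ValidationError("compare_groups needs at least two bundles")
    metric_sets = [
        tuple(sorted(t.select_dtypes("number").columns)) for t in bundles.values()
    ]
    if len(set(metric_sets)) != 1:
        raise ValidationError("bundles carry disjoint metric sets")
    rows = []
    for group, table in bundles.items():
        for _, r in table.iterrows():
            sample = r.get("sample", group)
            for metric in metric_sets[0]:
                rows.append({"sample": sample, "group": group,
                             "metric": metric, "value": r[metric]})
    return pd.DataFrame(rows, columns=["sample", "group", "metric", "value"])
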