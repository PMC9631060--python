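"""Non-imaging assay quantification.

Three independent procedures live here:

* **GR dose-response.**  Growth-rate-corrected drug response per Hafner's
  framework: with x0 the viability signal at treatment start, x_ctrl the
  vehicle control at treatment end and x(c) the treated signal,

      GR(c) = 2^{ log2(x(c)/x0) / log2(x_ctrl/x0) } − 1,

  so GR = 1 means no effect, 0 complete cytostasis and GR < 0 net cell
  death.  GR values are fitted with the 3-parameter sigmoid
  GR(c) = GR_inf + (1 − GR_inf) / (1 + (c/GEC50)^h) and GR50 — the
  concentration where the fitted curve crosses 0.5 — is solved
  analytically from the fit.

* **ΔΔCT fold changes** against a baseline condition with an internal
  reference gene: ΔCt = Ct_target − Ct_reference per sample,
  ΔΔCt = mean ΔCt(group) − mean ΔCt(baseline), fold = 2^(−ΔΔCt).

* **Cytokine-array normalization.**  Membrane spot intensities divided by
  the mean positive-reference-spot intensity of the same membrane (cancels
  exposure differences), duplicate spots averaged per analyte, and group
  fold changes taken against a baseline group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .images import DegenerateInputError, ValidationError


# ---------------------------------------------------------------------------
# GR metrics


def gr_value(x0: float, x_ctrl: float, x_c) -> np.ndarray | float:
    """Growth-rate inhibition value(s) for treated signal(s) ``x_c``."""
    x_c = np.asarray(x_c, dtype=float)
    if x0 <= 0 or x_ctrl <= 0 or np.any(x_c <= 0):
        raise ValidationError("viability signals must be positive")
    if x_ctrl == x0:
        raise DegenerateInputError(
            "control did not grow (x_ctrl == x0): GR undefined"
        )
    gr = 2.0 ** (np.log2(x_c / x0) / np.log2(x_ctrl / x0)) - 1.0
    return gr if gr.ndim else float(gr)


def gr_sigmoid(c, gr_inf, gec50, h):
    """Three-parameter GR dose-response curve with upper asymptote 1."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.where(c > 0, (c / gec50) ** h, 0.0)
    return gr_inf + (1.0 - gr_inf) / (1.0 + t)


def gr50_from_params(gr_inf: float, gec50: float, h: float) -> float:
    """Concentration where the fitted sigmoid crosses GR = 0.5.

    Missing (NaN) when the lower asymptote never reaches 0.5
    (``gr_inf >= 0.5``)."""
    if gr_inf >= 0.5:
        return float("nan")
    return float(gec50 * (0.5 / (0.5 - gr_inf)) ** (1.0 / h))


@dataclass
class GRCurve:
    """Per-concentration GR values plus fitted sigmoid parameters."""

    concentrations_uM: np.ndarray
    gr: np.ndarray
    gr_inf: float
    gec50_uM: float
    hill: float
    gr50_uM: float          # NaN when the curve never crosses 0.5
    residual_rms: float
    ic50_rel_uM: float = float("nan")  # 50 % relative-viability crossing

    def predict(self, c):
        return gr_sigmoid(c, self.gr_inf, self.gec50_uM, self.hill)


def _interp_crossing(c: np.ndarray, y: np.ndarray, target: float) -> float:
    """First log-linear interpolated crossing of y(c) through ``target``."""
    for i in range(1, len(c)):
        y0, y1 = y[i - 1], y[i]
        if (y0 - target) * (y1 - target) <= 0 and y0 != y1:
            c0 = max(c[i - 1], 1e-12)
            lc = np.log(c0) + (y0 - target) / (y0 - y1) * (np.log(c[i]) - np.log(c0))
            return float(np.exp(lc))
    return float("nan")


def fit_gr_curve(concentrations_uM, gr_values, x_ratio=None) -> GRCurve:
    """Least-squares fit of the GR sigmoid and analytic GR50.

    ``concentrations_uM`` and ``gr_values`` are paired per-concentration
    observations (replicates pre-averaged).  ``x_ratio`` may supply the
    companion relative-viability values x(c)/x_ctrl from which the 50 %
    relative-viability crossing is interpolated for comparison.
    """
    c = np.asarray(concentrations_uM, dtype=float)
    g = np.asarray(gr_values, dtype=float)
    if c.shape != g.shape:
        raise ValidationError("concentration and GR arrays differ in length")
    if np.unique(c).size < 4 or 0.0 not in c:
        raise ValidationError(
            "need ≥4 distinct concentrations including an untreated (0) point"
        )
    if not np.all(np.isfinite(g)):
        raise ValidationError("GR values must be finite")

    pos = c[c > 0]
    p0 = (float(min(g.min(), 0.0)), float(np.median(pos)), 1.0)
    lo = (-1.0, pos.min() / 100.0, 0.05)
    hi = (1.0, pos.max() * 100.0, 10.0)
    try:
        popt, _ = curve_fit(
            gr_sigmoid, c, g, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"GR sigmoid fit failed to converge: {exc}; "
            f"residuals at start {np.round(g - gr_sigmoid(c, *p0), 3)}"
        ) from exc
    gr_inf, gec50, h = map(float, popt)
    resid = g - gr_sigmoid(c, gr_inf, gec50, h)
    order = np.argsort(c)
    ic50 = float("nan")
    if x_ratio is not None:
        x_ratio = np.asarray(x_ratio, dtype=float)
        ic50 = _interp_crossing(c[order], x_ratio[order], 0.5)
    return GRCurve(
        concentrations_uM=c[order],
        gr=g[order],
        gr_inf=gr_inf,
        gec50_uM=gec50,
        hill=h,
        gr50_uM=gr50_from_params(gr_inf, gec50, h),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        ic50_rel_uM=ic50,
    )


def gr_from_table(table: pd.DataFrame) -> GRCurve:
    """GR curve from a tidy dose-response table.

    Expected columns: ``concentration_uM``, ``signal``, ``timepoint``
    (``start`` or ``end``) and ``role`` (``treated`` or ``control``).
    GR is computed per replicate, then averaged per concentration before
    fitting — matching triplicate plate reads.
    """
    need = {"concentration_uM", "signal", "timepoint", "role"}
    if not need.issubset(table.columns):
        raise ValidationError(f"dose-response table needs columns {sorted(need)}")
    x0 = table.query("timepoint == 'start'")["signal"].mean()
    x_ctrl = table.query("timepoint == 'end' and role == 'control'")["signal"].mean()
    if not (x0 > 0 and x_ctrl > 0):
        raise ValidationError("start / control signals missing or nonpositive")
    treated = table.query("timepoint == 'end' and role == 'treated'")
    per_rep = treated.assign(gr=lambda t: gr_value(x0, x_ctrl, t["signal"].to_numpy()))
    agg = per_rep.groupby("concentration_uM", as_index=False).agg(
        gr=("gr", "mean"), signal=("signal", "mean")
    )
    return fit_gr_curve(
        agg["concentration_uM"], agg["gr"], x_ratio=agg["signal"] / x_ctrl
    )


# ---------------------------------------------------------------------------
# qPCR ΔΔCT


def ddct_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "CD31",
    baseline: tuple[str, object] = ("EC", 0),
) -> pd.DataFrame:
    """ΔΔCT fold change of ``target_gene`` per (group, day).

    ``table`` columns: ``sample``, ``group``, ``day``, ``gene``, ``ct``.
    ΔCt = Ct_target − Ct_reference within each sample; ΔΔCt subtracts the
    mean ΔCt of the baseline (group, day); fold change = 2^(−ΔΔCt),
    reported as the geometric mean over replicate samples (equivalently
    2^(−mean ΔΔCt)).
    """
    need = {"sample", "group", "day", "gene", "ct"}
    if not need.issubset(table.columns):
        raise ValidationError(f"Ct table needs columns {sorted(need)}")
    if not np.all(np.isfinite(table["ct"])) or np.any(table["ct"] <= 0):
        raise ValidationError("Ct values must be finite and positive")
    wide = table.pivot_table(
        index=["sample", "group", "day"], columns="gene", values="ct"
    ).reset_index()
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns or wide[gene].isna().any():
            raise ValidationError(
                f"gene {gene!r} missing for one or more samples"
            )
    wide["dct"] = wide[target_gene] - wide[reference_gene]
    base = wide[(wide["group"] == baseline[0]) & (wide["day"] == baseline[1])]
    if base.empty:
        raise ValidationError(
            f"no baseline rows for group={baseline[0]!r}, day={baseline[1]!r}"
        )
    base_dct = base["dct"].mean()
    out = wide.groupby(["group", "day"], as_index=False).agg(
        mean_dct=("dct", "mean"), n=("dct", "size")
    )
    out["ddct"] = out["mean_dct"] - base_dct
    out["fold_change"] = 2.0 ** (-out["ddct"])
    out.insert(0, "gene", target_gene)
    return out[["gene", "group", "day", "n", "ddct", "fold_change"]]


# ---------------------------------------------------------------------------
# Cytokine arrays


def normalize_spots(
    spots: pd.DataFrame,
    spot_map: pd.DataFrame,
) -> pd.DataFrame:
    """Reference-spot normalization of membrane spot intensities.

    ``spots`` columns: ``membrane``, ``spot`` (id), ``intensity``
    (background-subtracted).  ``spot_map`` columns: ``spot``, ``analyte``
    (use ``"__reference__"`` for positive reference spots).  Each
    membrane's intensities are divided by that membrane's mean reference
    intensity; duplicate spots per analyte are averaged.  Returns a tidy
    (membrane, analyte, value) table.
    """
    need_s = {"membrane", "spot", "intensity"}
    need_m = {"spot", "analyte"}
    if not need_s.issubset(spots.columns) or not need_m.issubset(spot_map.columns):
        raise ValidationError("spot table or map missing required columns")
    merged = spots.merge(spot_map, on="spot", how="left")
    if merged["analyte"].isna().any():
        missing = merged.loc[merged["analyte"].isna(), "spot"].unique()
        raise ValidationError(f"spots without map entries: {list(missing)}")
    out_rows = []
    for membrane, mem in merged.groupby("membrane"):
        ref = mem.loc[mem["analyte"] == "__reference__", "intensity"]
        if ref.empty or ref.mean() <= 0:
            raise ValidationError(
                f"membrane {membrane!r}: missing or nonpositive reference spots"
            )
        norm = mem[mem["analyte"] != "__reference__"].copy()
        norm["value"] = norm["intensity"] / ref.mean()
        per_analyte = norm.groupby("analyte", as_index=False)["value"].mean()
        per_analyte.insert(0, "membrane", membrane)
        out_rows.append(per_analyte)
    return pd.concat(out_rows, ignore_index=True)


def secretome_fold_change(
    normalized: pd.DataFrame,
    groups: pd.DataFrame | dict,
    baseline_group: str = "GBM",
) -> pd.DataFrame:
    """Analyte × group fold changes against a baseline group.

    ``normalized`` is the output of :func:`normalize_spots`; ``groups``
    maps membrane → experimental group.  Per analyte, each group's mean
    normalized intensity is divided by the baseline group's; the baseline
    column is identically 1.  Analytes with zero baseline signal are
    reported NaN with a warning.
    """
    if isinstance(groups, dict):
        groups = pd.DataFrame(
            {"membrane": list(groups), "group": list(groups.values())}
        )
    df = normalized.merge(groups, on="membrane", how="left")
    if df["group"].isna().any():
        raise ValidationError("membranes without a group assignment")
    mean = df.pivot_table(index="analyte", columns="group", values="value",
                          aggfunc="mean")
    if baseline_group not in mean.columns:
        raise ValidationError(f"baseline group {baseline_group!r} not present")
    base = mean[baseline_group]
    if (base == 0).any():
        warnings.warn("analytes with zero baseline signal reported as NaN")
    fc = mean.div(base.replace(0, np.nan), axis=0)
    fc.columns.name = None
    return fc.reset_index()
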