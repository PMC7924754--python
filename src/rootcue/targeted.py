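"""Targeted quantification: calibration, MS-to-UV conversion, knockout
summaries and qPCR relative expression.

Benzoxazinoids are quantified from integrated UV signals at 265 nm against
external standards. Fits run through the origin by default (a blank has
zero signal), so the calibration slope is the closed form
``sum(x*y) / sum(x^2)`` and quantification is ``area / slope`` scaled by
extraction volume and tissue mass to ug per g fresh weight. Where a
compound's UV signal is too weak to be reliable, a compound-specific
MS-to-UV conversion factor (slope of UV ~ MS through the origin) predicts
the UV signal from the more sensitive MS trace; every quantified value
carries a provenance flag (measured vs predicted).

Relative gene expression uses the 2^-ddCt estimator: per-sample
delta-Ct = Ct(target) - Ct(reference), centered on the control-group mean
delta-Ct, and exponentiated base 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------
class CalibrationCurve(BaseEstimator):
    """Linear calibration of UV area against known standard concentrations.

    ``through_origin=True`` (default) fits area = slope * concentration by
    least squares (slope = sum(xy)/sum(x^2)); otherwise ordinary least
    squares with an intercept. ``predict`` inverts the curve: it maps UV
    areas back to concentrations.
    """

    def __init__(self, through_origin: bool = True):
        self.through_origin = through_origin

    def fit(self, concentration, uv_area):
        x = np.asarray(concentration, dtype=float)
        y = np.asarray(uv_area, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 calibration points")
        if np.allclose(x, x[0]):
            raise ValueError("degenerate standards: all concentrations equal")
        if self.through_origin:
            slope = float(np.sum(x * y) / np.sum(x * x))
            intercept = 0.0
        else:
            slope, intercept = np.polyfit(x, y, 1)
            slope, intercept = float(slope), float(intercept)
        if slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {slope:g}")
        self.slope_ = slope
        self.intercept_ = intercept
        return self

    def predict(self, uv_area):
        """Concentration (standard units) from UV area."""
        if not hasattr(self, "slope_"):
            raise RuntimeError("CalibrationCurve is not fitted")
        return (np.asarray(uv_area, dtype=float) - self.intercept_) / self.slope_


def fit_calibration(
    standards: pd.DataFrame, through_origin: bool = True
) -> dict[str, CalibrationCurve]:
    """Fit one :class:`CalibrationCurve` per compound.

    *standards* has columns ``compound``, ``concentration``, ``uv_area``.
    """
    if standards.empty:
        raise ValueError("empty standards table")
    curves = {}
    for comp, grp in standards.groupby("compound"):
        curves[str(comp)] = CalibrationCurve(through_origin).fit(
            grp["concentration"], grp["uv_area"]
        )
    return curves


# --------------------------------------------------------------------------
# MS-to-UV conversion
# --------------------------------------------------------------------------
class MsUvConverter(BaseEstimator):
    """Compound-specific MS-to-UV signal conversion factor.

    Fits UV ~ factor * MS through the origin on samples where both signals
    exceed a reliability floor; ``predict`` returns predicted UV areas for
    MS areas.
    """

    def __init__(self, floor: float = 0.0):
        self.floor = floor

    def fit(self, ms_area, uv_area):
        ms = np.asarray(ms_area, dtype=float)
        uv = np.asarray(uv_area, dtype=float)
        ok = (ms > self.floor) & (uv > self.floor)
        if ok.sum() < 3:
            raise ValueError(
                "need at least 3 reliable (UV, MS) pairs above the floor; "
                "collect more calibration data"
            )
        self.factor_ = float(np.sum(uv[ok] * ms[ok]) / np.sum(ms[ok] ** 2))
        self.n_pairs_ = int(ok.sum())
        return self

    def predict(self, ms_area):
        if not hasattr(self, "factor_"):
            raise RuntimeError("MsUvConverter is not fitted")
        return self.factor_ * np.asarray(ms_area, dtype=float)


def estimate_ms_uv_factor(ms_area, uv_area, floor: float = 0.0) -> float:
    """Closed-form conversion factor sum(uv*ms)/sum(ms^2) over reliable pairs."""
    return MsUvConverter(floor).fit(ms_area, uv_area).factor_


# --------------------------------------------------------------------------
# panel quantification
# --------------------------------------------------------------------------
def quantify_panel(
    panel: pd.DataFrame,
    standards: pd.DataFrame,
    uv_floor: float | None = None,
    extract_volume_ml: float = 1.0,
    curve_fallback: dict | None = None,
) -> pd.DataFrame:
    """Quantify a targeted panel to ug per g fresh weight.

    *panel* columns: ``compound``, ``uv_area``, ``ms_area``,
    ``tissue_mass_mg`` (plus any metadata, which is carried through).
    Compounds without their own standard may be mapped onto another
    compound's curve via *curve_fallback* (e.g. a glucoside without a
    standard quantified on its parent glucoside's curve).

    When *uv_floor* is given, samples whose measured UV area falls below it
    are quantified from MS-predicted UV signals using a per-compound
    MS-to-UV factor fitted on the reliable samples; the ``provenance``
    column records which route produced each value.
    """
    curves = fit_calibration(standards)
    fallback = curve_fallback or {}
    out = panel.copy()
    out["uv_used"] = out["uv_area"].astype(float)
    out["provenance"] = "measured-uv"

    if uv_floor is not None:
        for comp, grp in out.groupby("compound"):
            low = grp.index[grp["uv_area"] < uv_floor]
            if len(low) == 0:
                continue
            reliable = grp[grp["uv_area"] >= uv_floor]
            conv = MsUvConverter(floor=0.0).fit(
                reliable["ms_area"], reliable["uv_area"]
            )
            out.loc[low, "uv_used"] = conv.predict(out.loc[low, "ms_area"])
            out.loc[low, "provenance"] = "predicted-uv"

    for comp, grp in out.groupby("compound"):
        curve = curves.get(str(comp)) or curves.get(fallback.get(str(comp), ""))
        if curve is None:
            raise KeyError(f"no calibration curve for compound {comp!r}")
        conc_extract = curve.predict(grp["uv_used"])  # ug/mL in extract
        mass_g = grp["tissue_mass_mg"].to_numpy(dtype=float) / 1000.0
        out.loc[grp.index, "concentration"] = (
            conc_extract * extract_volume_ml / mass_g
        )
    return out


# --------------------------------------------------------------------------
# knockout summaries
# --------------------------------------------------------------------------
@dataclass
class ReductionSummary:
    overall_pct: float
    by_root_type: dict = field(default_factory=dict)
    by_compound: dict = field(default_factory=dict)


def percent_reduction(
    wt: pd.DataFrame, mutant: pd.DataFrame, value_col: str = "concentration"
) -> ReductionSummary:
    """Percent reduction of total metabolite levels in the mutant vs wild type.

    Computed on summed concentrations: overall, per root type (if a
    ``root_type`` column is present) and per compound. A wild-type total of
    zero leaves the corresponding entry undefined (NaN with a warning).
    """

    def _pct(wt_total: float, mut_total: float) -> float:
        if wt_total <= 0:
            warnings.warn("wild-type total is zero; reduction undefined",
                          stacklevel=3)
            return float("nan")
        return 100.0 * (1.0 - mut_total / wt_total)

    overall = _pct(wt[value_col].sum(), mutant[value_col].sum())
    by_root = {}
    if "root_type" in wt.columns:
        for root in sorted(wt["root_type"].unique()):
            by_root[root] = _pct(
                wt.loc[wt["root_type"] == root, value_col].sum(),
                mutant.loc[mutant["root_type"] == root, value_col].sum(),
            )
    by_comp = {}
    if "compound" in wt.columns:
        for comp in sorted(wt["compound"].unique()):
            by_comp[comp] = _pct(
                wt.loc[wt["compound"] == comp, value_col].sum(),
                mutant.loc[mutant["compound"] == comp, value_col].sum(),
            )
    return ReductionSummary(overall, by_root, by_comp)


# --------------------------------------------------------------------------
# qPCR relative expression
# --------------------------------------------------------------------------
def ddct(
    records: pd.DataFrame, control_group: str = "control"
) -> tuple[pd.DataFrame, dict]:
    """2^-ddCt relative expression per sample, normalized to *control_group*.

    *records* columns: ``sample_id``, ``group``, ``ct_target``,
    ``ct_reference``. Samples missing either Ct are dropped with a
    warning. Returns the per-sample frame (with ``delta_ct``,
    ``delta_delta_ct`` and ``rel_expression``) plus a summary dict with
    group mean expressions and percent knockdown of every non-control
    group.
    """
    df = records.copy()
    missing = df["ct_target"].isna() | df["ct_reference"].isna()
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} sample(s) with missing Ct",
            stacklevel=2,
        )
        df = df[~missing]
    if (df[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    if not (df["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} is empty")

    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    control_mean = df.loc[df["group"] == control_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - control_mean
    df["rel_expression"] = np.power(2.0, -df["delta_delta_ct"])

    group_means = df.groupby("group")["rel_expression"].mean().to_dict()
    control_expr = group_means[control_group]
    knockdown = {
        g: 100.0 * (1.0 - m / control_expr)
        for g, m in group_means.items()
        if g != control_group
    }
    summary = {
        "group_mean_expression": group_means,
        "percent_knockdown": knockdown,
        "control_group": control_group,
    }
    return df, summary
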