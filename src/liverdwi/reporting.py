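"""Cohort-level report tables.

Builds the four standard report tables of the diagnostic analysis from a
measurements table (one row per patient-slice ROI) and a clinical table
(one row per patient):

* table 1 — clinical/laboratory group comparison (median (IQR), Mann-Whitney
  or Fisher p);
* table 2 — ROI area and diffusion parameters per group, estimated means
  with 95% CIs from the repeated-measures mixed model;
* table 3 — diagnostic performance per marker (Youden cutoff, sensitivity/
  specificity with exact CIs, AUC with DeLong CI);
* table 4 — pairwise DeLong p-values comparing marker ROC curves.

Units follow the conventional presentation: diffusion coefficients in
1e-3 mm^2/s (the measurements frame already carries them on that scale),
f in percent, alpha and AUC dimensionless.

Unit of analysis for ROC: imaging markers are evaluated per measurement
(every ROI row counts), laboratory markers per patient — matching how exact
sensitivity/specificity denominators are reported for each marker class.
For the *paired* DeLong matrix every marker must score the same
observations, so lab values are broadcast to their patient's measurement
rows there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_inference import (
    ContingencyTable2x2,
    DiagnosticResult,
    delong_paired_test,
    fisher_exact_2x2,
    lmm_group_comparison,
    logistic_combined_auc,
    mann_whitney_u_exact,
    roc_with_youden,
)

__all__ = [
    "LAB_COLUMNS",
    "IMAGING_MARKERS",
    "MARKER_ORIENTATION",
    "build_table1",
    "build_table2",
    "build_table3",
    "build_table4",
    "combined_marker_result",
    "diagnostic_to_row",
]

LAB_COLUMNS = ["AST", "ALT", "total_bilirubin", "direct_bilirubin", "ALP", "GGT"]

#: Markers entering ROC analysis and the side of the cutoff indicating BA.
MARKER_ORIENTATION: dict[str, str] = {
    "GGT": "higher",
    "ADC10": "lower",
    "ADC2": "lower",
    "Dstar": "lower",
    "f": "lower",
    "DDC": "lower",
    "alpha": "higher",
}
IMAGING_MARKERS = [m for m in MARKER_ORIENTATION if m != "GGT"]

POSITIVE_GROUP = "BA"


def _median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def build_table1(clinical: pd.DataFrame) -> pd.DataFrame:
    """Clinical and laboratory comparison between the two groups."""
    groups = [POSITIVE_GROUP] + [g for g in clinical["group"].unique()
                                 if g != POSITIVE_GROUP]
    ba = clinical[clinical["group"] == groups[0]]
    non = clinical[clinical["group"] == groups[1]]
    rows = []

    v_ba, v_non = ba["age_weeks"].to_numpy(), non["age_weeks"].to_numpy()
    _, p = mann_whitney_u_exact(v_ba, v_non)
    rows.append({"variable": "Age (weeks)", groups[0]: _median_iqr(v_ba),
                 groups[1]: _median_iqr(v_non), "p_value": p,
                 "test": "mann-whitney"})

    tab = ContingencyTable2x2(
        a=int((ba["sex"] == "M").sum()), b=int((ba["sex"] == "F").sum()),
        c=int((non["sex"] == "M").sum()), d=int((non["sex"] == "F").sum()))
    rows.append({"variable": "Gender (M:F)",
                 groups[0]: f"{tab.a}:{tab.b}", groups[1]: f"{tab.c}:{tab.d}",
                 "p_value": fisher_exact_2x2(tab), "test": "fisher"})

    for lab in LAB_COLUMNS:
        v_ba, v_non = ba[lab].to_numpy(), non[lab].to_numpy()
        _, p = mann_whitney_u_exact(v_ba, v_non)
        rows.append({"variable": lab, groups[0]: _median_iqr(v_ba),
                     groups[1]: _median_iqr(v_non), "p_value": p,
                     "test": "mann-whitney"})
    return pd.DataFrame(rows)


#: table-2 rows: measurement column -> (label, display transform)
_TABLE2_ROWS = [
    ("area_mm2", "Area of ROIs (mm^2)", 1.0),
    ("ADC10", "ADC 10 (1e-3 mm^2/s)", 1.0),
    ("ADC2", "ADC 2 (1e-3 mm^2/s)", 1.0),
    ("D", "D (1e-3 mm^2/s)", 1.0),
    ("Dstar", "D* (1e-3 mm^2/s)", 1.0),
    ("f", "f (%)", 100.0),
    ("DDC", "DDC (1e-3 mm^2/s)", 1.0),
    ("alpha", "alpha", 1.0),
]


def build_table2(measurements: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures group comparison of ROI area and DWI parameters.

    ``measurements`` must carry patient_id, group, area_mm2 and the seven
    parameter columns (coefficients on the 1e-3 mm^2/s scale, f and alpha
    as fractions).
    """
    groups = [POSITIVE_GROUP] + [g for g in measurements["group"].unique()
                                 if g != POSITIVE_GROUP]
    rows = []
    for col, label, scale in _TABLE2_ROWS:
        df = measurements.copy()
        df[col] = df[col] * scale
        res = lmm_group_comparison(df, col)
        row = {"variable": label}
        for g in groups:
            est, lo, hi = res.estimates[g]
            row[g] = f"{est:.3f} ({lo:.3f}-{hi:.3f})"
        row["p_value"] = res.p_value
        row["method"] = res.method
        rows.append(row)
    return pd.DataFrame(rows)


def _marker_scores(marker: str, measurements: pd.DataFrame,
                   clinical: pd.DataFrame, unit: str):
    """Scores and labels for one marker at the requested unit of analysis."""
    if marker == "GGT":
        if unit == "per_patient":
            df = clinical
            scores = df["GGT"].to_numpy(dtype=float)
        else:  # broadcast to measurement rows
            merged = measurements.merge(clinical[["patient_id", "GGT"]],
                                        on="patient_id", how="left",
                                        suffixes=("", "_clin"))
            col = "GGT_clin" if "GGT_clin" in merged.columns else "GGT"
            df, scores = merged, merged[col].to_numpy(dtype=float)
    else:
        if unit == "per_patient":
            df = measurements.groupby(["patient_id", "group"], sort=False)[
                marker].mean().reset_index()
        else:
            df = measurements
        scores = df[marker].to_numpy(dtype=float)
        if marker == "f":
            scores = scores * 100.0  # cutoffs conventionally printed in %
    labels = (df["group"] == POSITIVE_GROUP).to_numpy()
    return scores, labels


def diagnostic_to_row(res: DiagnosticResult) -> dict:
    return {
        "marker": res.marker,
        "criterion": res.criterion,
        "sensitivity": (f"{res.sensitivity:.1f} "
                        f"({res.sensitivity_ci[0]:.1f}-{res.sensitivity_ci[1]:.1f})"),
        "specificity": (f"{res.specificity:.1f} "
                        f"({res.specificity_ci[0]:.1f}-{res.specificity_ci[1]:.1f})"),
        "auc": f"{res.auc:.3f} ({res.auc_ci[0]:.3f}-{res.auc_ci[1]:.3f})",
        "n_pos": res.n_pos, "n_neg": res.n_neg,
        "flags": ";".join(res.flags),
    }


def build_table3(measurements: pd.DataFrame, clinical: pd.DataFrame,
                 imaging_unit: str = "per_measurement",
                 lab_unit: str = "per_patient") -> pd.DataFrame:
    """Per-marker diagnostic performance (Youden cutoff + AUC)."""
    rows = []
    for marker, orientation in MARKER_ORIENTATION.items():
        unit = lab_unit if marker == "GGT" else imaging_unit
        scores, labels = _marker_scores(marker, measurements, clinical, unit)
        res = roc_with_youden(scores, labels, orientation, marker=marker)
        rows.append(diagnostic_to_row(res))
    return pd.DataFrame(rows)


def build_table4(measurements: pd.DataFrame,
                 clinical: pd.DataFrame) -> pd.DataFrame:
    """Pairwise DeLong p-values between marker ROC curves.

    All markers are scored per measurement (lab values broadcast to their
    patient's rows) so the paired test sees the same observations.  Scores
    are sign-flipped for lower-indicates-BA markers so every column is
    oriented the same way before comparison.
    """
    markers = list(MARKER_ORIENTATION)
    oriented = {}
    labels = None
    for marker in markers:
        scores, lab = _marker_scores(marker, measurements, clinical,
                                     "per_measurement")
        if MARKER_ORIENTATION[marker] == "lower":
            scores = -scores
        oriented[marker] = scores
        labels = lab
    mat = pd.DataFrame(index=markers, columns=markers, dtype=float)
    for i, a in enumerate(markers):
        for bm in markers[i + 1:]:
            p = delong_paired_test(oriented[a], oriented[bm], labels)["p"]
            mat.loc[a, bm] = p
    return mat


def combined_marker_result(measurements: pd.DataFrame,
                           clinical: pd.DataFrame) -> DiagnosticResult:
    """Logistic combination of patient-mean ADC2 and gamma-GT."""
    per_patient = measurements.groupby(["patient_id", "group"], sort=False)[
        "ADC2"].mean().reset_index()
    merged = per_patient.merge(clinical[["patient_id", "GGT"]], on="patient_id")
    labels = (merged["group"] == POSITIVE_GROUP).to_numpy()
    return logistic_combined_auc(merged["ADC2"], merged["GGT"], labels,
                                 marker="ADC2+GGT")
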