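"""Cohort I/O, scoring and cohort-level statistics.

The pipeline's on-disk format is a comma-separated UTF-8 long table with a
required header::

    patient_id, arm, outcome, fatigue, abdominal_distension, anorexia,
    jaundice, lower_limb_oedema, indicator, pre, post

one row per (patient, indicator).  Missing pre/post values are allowed
(the indicator is skipped in scoring); non-numeric or non-positive lab
values reject the row, which is reported with its line number.

On top of scoring, the module provides the cohort-level statistics a
treatment-evaluation study reports:

* per-indicator per-arm comparison tables (pre/post mean (SD), paired-test
  p value, group QD value) — both aggregations of the group QD value are
  offered, the mean of per-patient golden logarithms and the golden
  logarithm of the two group means, since they genuinely differ;
* the association between the composite QD score and the MELD comparator
  (Pearson r, p, OLS line);
* outcome-group contrasts (mean (SD) per recovered / dropped-out / died
  group) and per-clinical-status-flag two-group tests, pooled across arms.

Statistical tests default to t-tests (paired within arm, Welch between
groups) and are switchable to Wilcoxon / Mann-Whitney; no multiple-testing
correction is applied by default, with a Benjamini-Hochberg switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .golden import ThresholdScheme, golden_log
from .meld import meld_score, normalize_units
from .registry import IndicatorSpec, default_registry
from .scoring import LiverRule, PairedMeasurement, PatientPanel, score_patient
from .simulate import STATUS_FLAGS

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "score_cohort",
    "group_qd_value",
    "paired_change_test",
    "comparison_table",
    "qd_meld_association",
    "outcome_contrast",
]

#: Required column order of the cohort long table.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "arm",
    "outcome",
    *STATUS_FLAGS,
    "indicator",
    "pre",
    "post",
)

#: Indicator names feeding the MELD comparator, with analyte/unit for conversion.
_MELD_SOURCES: tuple[tuple[str, str, str], ...] = (
    ("creatinine", "creatinine", "umol_per_L"),
    ("total_bilirubin", "bilirubin", "umol_per_L"),
    ("international_normalized_ratio", "", "ratio"),
)


def read_cohort(path: str | Path, *, strict: bool = False) -> pd.DataFrame:
    """Read and validate a cohort long table.

    Rows whose pre/post is present but non-numeric or non-positive are
    rejected; the report of rejected rows (with 1-based file line numbers)
    is attached as ``df.attrs['row_errors']``.  With ``strict=True`` any
    rejected row raises :class:`InputError`.  A missing column is always a
    hard error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    df = df[list(COHORT_COLUMNS)]

    errors: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for col in ("pre", "post"):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad_numeric = num.isna() & raw.notna()
        bad_sign = num.notna() & (num <= 0)
        for idx in df.index[bad_numeric | bad_sign]:
            line = idx + 2  # header is line 1
            errors.append(
                f"line {line}: indicator {df.at[idx, 'indicator']!r} has invalid "
                f"{col} value {raw[idx]!r} (must be a positive number)"
            )
        keep &= ~(bad_numeric | bad_sign).to_numpy()
        df[col] = num
    dup = df.duplicated(subset=["patient_id", "indicator"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "indicator"]].drop_duplicates()
        errors.extend(
            f"duplicate (patient_id, indicator) = ({p!r}, {i!r})"
            for p, i in pairs.itertuples(index=False)
        )
        keep &= ~dup.to_numpy()
    if errors and strict:
        raise InputError(f"{path}: " + "; ".join(errors))
    out = df[keep].reset_index(drop=True)
    out.attrs["row_errors"] = errors
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (UTF-8, header, repr-roundtrip floats)."""
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False)


def _patient_meld(measurements: Mapping[str, tuple[float, float]], when: str) -> float:
    idx = 0 if when == "pre" else 1
    values = {}
    for indicator, analyte, unit in _MELD_SOURCES:
        if indicator not in measurements:
            return float("nan")
        v = measurements[indicator][idx]
        if v is None or not math.isfinite(v):
            return float("nan")
        values[indicator] = v if unit == "ratio" else normalize_units(v, analyte, unit)
    return meld_score(
        values["creatinine"],
        values["total_bilirubin"],
        values["international_normalized_ratio"],
    )


def score_cohort(
    cohort: pd.DataFrame,
    registry: Mapping[str, IndicatorSpec] | None = None,
    scheme: ThresholdScheme | str | None = None,
    liver_rule: LiverRule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every patient of a cohort table.

    Returns ``(scores, breakdown)``: one row per patient with the composite
    QD total, the D/E gates and MELD before/after (computed from the
    creatinine, total-bilirubin and INR rows, converted to mg/dL), and the
    per-indicator long breakdown (A, B, C, L_tau, product).
    """
    if cohort.empty:
        raise InputError("empty cohort: nothing to score")
    registry = registry if registry is not None else default_registry()
    score_rows, breakdown_rows = [], []
    for patient_id, grp in cohort.groupby("patient_id", sort=True):
        measurements = tuple(
            PairedMeasurement(r.indicator, r.pre, r.post)
            for r in grp.itertuples(index=False)
        )
        first = grp.iloc[0]
        panel = PatientPanel(
            patient_id=str(patient_id),
            measurements=measurements,
            arm=first["arm"],
            outcome=first["outcome"],
        )
        bd = score_patient(panel, registry, scheme=scheme, liver_rule=liver_rule)
        pairs = {
            m.indicator: (m.pre, m.post)
            for m in measurements
            if pd.notna(m.pre) and pd.notna(m.post)
        }
        row = {
            "patient_id": panel.patient_id,
            "arm": panel.arm,
            "outcome": panel.outcome,
            "qd_total": bd.total,
            "non_liver_sum": bd.non_liver_sum,
            "liver_contribution": bd.liver_contribution,
            "d_gate": bd.d_gate,
            "e_gate": bd.e_gate,
            "n_scored": len(bd.per_indicator),
            "n_skipped": len(bd.skipped),
            "meld_pre": _patient_meld(pairs, "pre"),
            "meld_post": _patient_meld(pairs, "post"),
        }
        row["meld_delta"] = row["meld_pre"] - row["meld_post"]
        for flag in STATUS_FLAGS:
            row[flag] = first[flag] if flag in grp.columns else None
        score_rows.append(row)
        breakdown_rows.extend(
            {
                "patient_id": panel.patient_id,
                "indicator": s.indicator,
                "a": s.a,
                "b": s.b,
                "c": s.c,
                "l_tau": s.l_tau,
                "product": s.product,
                "is_liver_panel": s.is_liver_panel,
            }
            for s in bd.per_indicator
        )
    return pd.DataFrame(score_rows), pd.DataFrame(breakdown_rows)


def _select(cohort: pd.DataFrame, indicator: str, arm: str | None) -> pd.DataFrame:
    sel = cohort[cohort["indicator"] == indicator]
    if arm is not None:
        sel = sel[sel["arm"] == arm]
    sel = sel.dropna(subset=["pre", "post"])
    if sel.empty:
        raise InputError(f"no complete pairs for indicator {indicator!r} in arm {arm!r}")
    return sel


def group_qd_value(
    cohort: pd.DataFrame,
    indicator: str,
    arm: str | None = None,
    aggregation: str = "mean_of_patient_ltau",
) -> float:
    """Group-level QD value for one indicator in one arm.

    Two aggregations exist and differ in general:

    * ``mean_of_patient_ltau`` — average the per-patient golden logarithms;
    * ``ltau_of_group_means`` — golden logarithm of the pre-mean / post-mean
      pair.
    """
    sel = _select(cohort, indicator, arm)
    if aggregation == "mean_of_patient_ltau":
        return float(
            np.mean([golden_log(r.pre, r.post) for r in sel.itertuples(index=False)])
        )
    if aggregation == "ltau_of_group_means":
        return golden_log(float(sel["pre"].mean()), float(sel["post"].mean()))
    raise InputError(
        f"unknown aggregation {aggregation!r}; expected 'mean_of_patient_ltau' "
        "or 'ltau_of_group_means'"
    )


def paired_change_test(
    cohort: pd.DataFrame,
    indicator: str,
    arm: str | None = None,
    method: str = "t",
) -> tuple[float, float]:
    """Paired pre-vs-post test for one indicator in one arm.

    ``method='t'`` is a two-sided paired t-test; ``'wilcoxon'`` the signed-
    rank alternative.  All-zero differences return (0.0, 1.0).
    """
    sel = _select(cohort, indicator, arm)
    if len(sel) < 2:
        raise InputError(
            f"paired test needs >= 2 complete pairs, got {len(sel)} for {indicator!r}"
        )
    pre, post = sel["pre"].to_numpy(), sel["post"].to_numpy()
    if np.all(pre == post):
        return 0.0, 1.0
    if method == "t":
        res = stats.ttest_rel(pre, post)
    elif method == "wilcoxon":
        res = stats.wilcoxon(pre, post)
    else:
        raise InputError(f"unknown method {method!r}; expected 't' or 'wilcoxon'")
    return float(res.statistic), float(res.pvalue)


def comparison_table(
    cohort: pd.DataFrame,
    arms: tuple[str, ...] | None = None,
    method: str = "t",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-indicator per-arm summary: pre/post mean (SD), p, both QD values.

    One row per (indicator, arm).  ``fdr=True`` adds Benjamini-Hochberg
    adjusted p values across indicators within each arm.
    """
    if arms is None:
        arms = tuple(sorted(cohort["arm"].dropna().unique()))
    rows = []
    for arm in arms:
        for indicator in sorted(cohort.loc[cohort["arm"] == arm, "indicator"].unique()):
            sel = _select(cohort, indicator, arm)
            stat, p = paired_change_test(cohort, indicator, arm, method=method)
            rows.append(
                {
                    "arm": arm,
                    "indicator": indicator,
                    "n": len(sel),
                    "pre_mean": sel["pre"].mean(),
                    "pre_sd": sel["pre"].std(ddof=1),
                    "post_mean": sel["post"].mean(),
                    "post_sd": sel["post"].std(ddof=1),
                    "statistic": stat,
                    "p_value": p,
                    "qd_mean_patient_ltau": group_qd_value(
                        cohort, indicator, arm, "mean_of_patient_ltau"
                    ),
                    "qd_ltau_of_means": group_qd_value(
                        cohort, indicator, arm, "ltau_of_group_means"
                    ),
                }
            )
    table = pd.DataFrame(rows)
    if fdr:
        table["p_adjusted"] = np.nan
        for arm in arms:
            mask = table["arm"] == arm
            table.loc[mask, "p_adjusted"] = stats.false_discovery_control(
                table.loc[mask, "p_value"]
            )
    return table


@dataclass(frozen=True)
class AssociationResult:
    """Pearson correlation and OLS line between two per-patient scores."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    defined: bool = True


def qd_meld_association(
    scores: pd.DataFrame, meld_col: str = "meld_delta"
) -> AssociationResult:
    """Association between the composite QD score and the MELD comparator.

    Defaults to the MELD improvement (pre minus post), the natural
    comparator for a change score; any numeric column of the score table
    can be selected.  Returns r undefined (NaN, ``defined=False``) when
    either score has zero variance.
    """
    sel = scores.dropna(subset=["qd_total", meld_col])
    if len(sel) < 3:
        raise InputError(f"association needs >= 3 patients with both scores, got {len(sel)}")
    x = sel[meld_col].to_numpy(dtype=float)
    y = sel["qd_total"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(
            r=float("nan"), p_value=float("nan"), slope=float("nan"),
            intercept=float("nan"), n=len(sel), defined=False,
        )
    fit = stats.linregress(x, y)
    return AssociationResult(
        r=float(fit.rvalue), p_value=float(fit.pvalue), slope=float(fit.slope),
        intercept=float(fit.intercept), n=len(sel),
    )


def outcome_contrast(
    scores: pd.DataFrame, method: str = "t"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome-group summaries and clinical-status-flag contrasts.

    Returns ``(groups, flags)``.  ``groups`` has mean (SD) of the composite
    QD score per outcome label (SD absent for n == 1; empty groups are
    omitted).  ``flags`` tests, per clinical-status flag and pooled across
    arms, improved vs deteriorated-or-unchanged patients (Welch t by
    default, ``method='mannwhitney'`` for the rank alternative).
    """
    if scores.empty:
        raise InputError("empty score table")
    group_rows = []
    for outcome in ("recovered", "dropped_out", "died"):
        grp = scores.loc[scores["outcome"] == outcome, "qd_total"]
        if grp.empty:
            continue
        group_rows.append(
            {
                "outcome": outcome,
                "n": len(grp),
                "mean": grp.mean(),
                "sd": grp.std(ddof=1) if len(grp) > 1 else float("nan"),
            }
        )
    groups = pd.DataFrame(group_rows)

    flag_rows = []
    for flag in STATUS_FLAGS:
        if flag not in scores.columns:
            continue
        improved = scores.loc[scores[flag] == "improved", "qd_total"]
        worse = scores.loc[scores[flag] == "deteriorated_or_unchanged", "qd_total"]
        row = {
            "flag": flag,
            "n_improved": len(improved),
            "improved_mean": improved.mean() if len(improved) else float("nan"),
            "improved_sd": improved.std(ddof=1) if len(improved) > 1 else float("nan"),
            "n_worse": len(worse),
            "worse_mean": worse.mean() if len(worse) else float("nan"),
            "worse_sd": worse.std(ddof=1) if len(worse) > 1 else float("nan"),
        }
        if len(improved) >= 2 and len(worse) >= 2:
            if method == "t":
                res = stats.ttest_ind(improved, worse, equal_var=False)
            elif method == "mannwhitney":
                res = stats.mannwhitneyu(improved, worse, alternative="two-sided")
            else:
                raise InputError(f"unknown method {method!r}")
            row["statistic"], row["p_value"] = float(res.statistic), float(res.pvalue)
        else:
            row["statistic"] = row["p_value"] = float("nan")
        flag_rows.append(row)
    return groups, pd.DataFrame(flag_rows)
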