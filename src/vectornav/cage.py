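"""Orientation-cage analysis pipeline.

Ingests tabular cage records (one row per one-hour funnel test), applies
the study's inclusion rule, keeps one test per bird per diagram, forms the
reported experimental groups, and emits every group statistic and pairwise
comparison of the published analysis: group mean vectors with Rayleigh
tests and 95% confidence intervals, mean-direction comparisons (Mardia's
one-way classification F when both samples are directed, Watson's U2 when
either is random), concentration-homogeneity tests, comparisons against
the mean sun azimuth, and activity chi-square tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import circstats as cs

REQUIRED_COLUMNS = [
    "bird_id", "age", "capture_window", "sky", "fat_score", "bearing",
    "activity_score", "concentration_score", "session_date",
]

AGES = {"adult", "juvenile"}
WINDOWS = {"early", "late"}
SKIES = {"clear", "overcast_natural", "overcast_simulated"}

# (label, age filter, window filter, sky class) -- sky class 'overcast'
# pools natural and simulated overcast, as in the published diagrams.
GROUP_DEFS = [
    ("adult_clear", "adult", None, "clear"),
    ("all_juv_clear", "juvenile", None, "clear"),
    ("all_juv_overcast", "juvenile", None, "overcast"),
    ("early_juv_clear", "juvenile", "early", "clear"),
    ("late_juv_clear", "juvenile", "late", "clear"),
    ("early_juv_overcast", "juvenile", "early", "overcast"),
    ("late_juv_overcast", "juvenile", "late", "overcast"),
]

# Mean-direction comparisons reported by the study.
MEAN_COMPARISONS = [
    ("adult_clear", "early_juv_clear"),
    ("early_juv_clear", "early_juv_overcast"),
    ("late_juv_clear", "adult_clear"),
    ("late_juv_clear", "early_juv_clear"),
    ("late_juv_overcast", "late_juv_clear"),
]
# Scatter (concentration) comparisons.
CONCENTRATION_COMPARISONS = [
    ("adult_clear", "early_juv_clear"),
    ("early_juv_clear", "early_juv_overcast"),
]
# Cells with a fat-vs-lean orientation comparison (early birds only; late
# birds had too few fat individuals).
FAT_COMPARISON_GROUPS = ["adult_clear", "early_juv_clear", "early_juv_overcast"]

MIN_GROUP_N = 5


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the documented header and per-row value domains.

    Raises ValueError naming the first offending row.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = records.copy()
    for idx, row in df.iterrows():
        if row["age"] not in AGES:
            raise ValueError(f"row {idx}: bad age {row['age']!r}")
        if row["capture_window"] not in WINDOWS:
            raise ValueError(f"row {idx}: bad capture_window {row['capture_window']!r}")
        if row["sky"] not in SKIES:
            raise ValueError(f"row {idx}: bad sky {row['sky']!r}")
        try:
            bearing = float(row["bearing"])
        except (TypeError, ValueError):
            raise ValueError(f"row {idx}: bearing {row['bearing']!r} not numeric") from None
        if bearing % 5.0 != 0.0:
            raise ValueError(f"row {idx}: bearing {bearing} not a multiple of 5 degrees")
        if not 0 <= int(row["fat_score"]) <= 9:
            raise ValueError(f"row {idx}: fat_score {row['fat_score']} outside 0..9")
        for col in ("activity_score", "concentration_score"):
            if not 0 <= int(row[col]) <= 4:
                raise ValueError(f"row {idx}: {col} {row[col]} outside 0..4")
    return df


def include_record(record) -> bool:
    """Inclusion rule: both scores >= 1 and their sum >= 3."""
    a = int(record["activity_score"])
    c = int(record["concentration_score"])
    return a >= 1 and c >= 1 and (a + c) >= 3


def fat_class(fat_score: int) -> str:
    """'fat' for visual fat score >= 3, else 'lean'."""
    score = int(fat_score)
    if not 0 <= score <= 9:
        raise ValueError(f"fat score {score} outside the 0..9 scale")
    return "fat" if score >= 3 else "lean"


def dedupe_per_group(records: pd.DataFrame) -> pd.DataFrame:
    """One record per bird: the chronologically first included test.

    Records must already be inclusion-filtered and belong to one group.
    Ties on date/time resolve by stable input order.
    """
    if records.empty:
        return records
    sort_cols = ["session_date"] + (
        ["session_time_utc"] if "session_time_utc" in records.columns else []
    )
    ordered = records.sort_values(sort_cols, kind="stable")
    return ordered.drop_duplicates(subset="bird_id", keep="first")


def _sky_class(sky: pd.Series) -> pd.Series:
    return sky.map(lambda s: "overcast" if s.startswith("overcast") else s)


def _group_mask(df: pd.DataFrame, age, window, skyclass):
    mask = pd.Series(True, index=df.index)
    if age is not None:
        mask &= df["age"] == age
    if window is not None:
        mask &= df["capture_window"] == window
    if skyclass is not None:
        mask &= _sky_class(df["sky"]) == skyclass
    return mask


@dataclass
class GroupResult:
    label: str
    n: int
    alpha: Optional[float]
    r: float
    rayleigh_p: Optional[float]
    ci: Optional[tuple]
    sun_azimuth: Optional[float]
    sun_outside_ci: Optional[bool]
    sample: Optional[cs.CircularSample]
    skipped: bool = False


def _group_result(label: str, sub: pd.DataFrame) -> GroupResult:
    n = len(sub)
    if n < MIN_GROUP_N:
        return GroupResult(label, n, None, 0.0, None, None, None, None, None, True)
    sample = cs.CircularSample(sub["bearing"].to_numpy(float), label=label)
    alpha, r = cs.mean_vector(sample)
    p = cs.rayleigh_p(n, r)
    ci = None
    sun_az = float(sub["sun_azimuth"].mean()) if "sun_azimuth" in sub.columns else None
    outside = None
    if p < 0.05:
        try:
            ci = cs.mean_ci95(sample)
            if sun_az is not None:
                outside = not cs.direction_in_ci(sample, sun_az)
        except ValueError:
            ci = None
    return GroupResult(label, n, alpha, r, p, ci, sun_az, outside, sample)


def _choose_mean_test(a: GroupResult, b: GroupResult):
    """Watson's U2 when either sample is random (Rayleigh p >= 0.05),
    Mardia's one-way classification F otherwise."""
    if a.rayleigh_p >= 0.05 or b.rayleigh_p >= 0.05:
        return "watson_u2", cs.watson_u2(a.sample, b.sample)
    return "mardia_f", cs.mardia_classification_f(a.sample, b.sample)


def run_analysis(records: pd.DataFrame) -> dict:
    """Full pipeline: validation, inclusion, dedupe, groups, comparisons.

    Returns a dict with 'groups' and 'comparisons' DataFrames, the
    'activity_tables' chi-square results, and the per-group dedup'd
    record sets under 'group_records'.  Deterministic for a given input.
    """
    df = validate_records(records)
    included = df[df.apply(include_record, axis=1)]

    groups: dict[str, GroupResult] = {}
    group_records: dict[str, pd.DataFrame] = {}
    for label, age, window, skyclass in GROUP_DEFS:
        sub = dedupe_per_group(included[_group_mask(included, age, window, skyclass)])
        group_records[label] = sub
        groups[label] = _group_result(label, sub)

    group_rows = []
    for g in groups.values():
        group_rows.append({
            "group": g.label, "n": g.n, "alpha": g.alpha, "r": g.r,
            "rayleigh_p": g.rayleigh_p,
            "ci_low": g.ci[0] if g.ci else None,
            "ci_high": g.ci[1] if g.ci else None,
            "mean_sun_azimuth": g.sun_azimuth,
            "sun_outside_ci": g.sun_outside_ci,
            "skipped": g.skipped,
        })

    comp_rows = []

    def _add(kind, la, lb, test_name, result):
        comp_rows.append({
            "comparison": kind, "group_a": la, "group_b": lb, "test": test_name,
            "statistic": result.statistic if result else None,
            "df": str(result.df) if result else None,
            "p_value": result.p_value if result else None,
        })

    for la, lb in MEAN_COMPARISONS:
        a, b = groups[la], groups[lb]
        if a.skipped or b.skipped:
            _add("mean_direction", la, lb, "skipped (group too small)", None)
            continue
        try:
            name, res = _choose_mean_test(a, b)
            _add("mean_direction", la, lb, name, res)
        except ValueError as err:
            _add("mean_direction", la, lb, f"skipped ({err})", None)

    for la, lb in CONCENTRATION_COMPARISONS:
        a, b = groups[la], groups[lb]
        if a.skipped or b.skipped:
            _add("concentration", la, lb, "skipped (group too small)", None)
            continue
        try:
            res = cs.concentration_homogeneity(a.sample, b.sample)
            _add("concentration", la, lb, "mardia_concentration", res)
        except ValueError as err:
            _add("concentration", la, lb, f"skipped ({err})", None)

    # fat vs lean within early-season cells
    for label in FAT_COMPARISON_GROUPS:
        sub = group_records[label]
        if sub.empty:
            continue
        fat = sub[sub["fat_score"].astype(int) >= 3]
        lean = sub[sub["fat_score"].astype(int) < 3]
        if len(fat) < MIN_GROUP_N or len(lean) < MIN_GROUP_N:
            _add("fat_vs_lean", label, label, "skipped (class too small)", None)
            continue
        ga = _group_result(f"{label}_fat", fat)
        gb = _group_result(f"{label}_lean", lean)
        if ga.skipped or gb.skipped:
            _add("fat_vs_lean", label, label, "skipped (class too small)", None)
            continue
        try:
            name, res = _choose_mean_test(ga, gb)
            _add("fat_vs_lean", f"{label}_fat", f"{label}_lean", name, res)
        except ValueError as err:
            _add("fat_vs_lean", f"{label}_fat", f"{label}_lean", f"skipped ({err})", None)

    comparisons = pd.DataFrame(comp_rows)

    activity_tables = _activity_chisq(df)

    return {
        "groups": pd.DataFrame(group_rows),
        "comparisons": comparisons,
        "activity_tables": activity_tables,
        "group_records": group_records,
    }


def _activity_chisq(df: pd.DataFrame) -> dict:
    """Chi-square tests on counts of active vs inactive tests.

    'Inactive' is activity score 0 (fewer than 40 scratches).  Tables:
    experimental category x activity, sky condition x activity, capture
    period x activity, and fat class x activity; degenerate tables are
    skipped with a reason string.
    """
    work = df.copy()
    work["active"] = work["activity_score"].astype(int) >= 1
    work["skyclass"] = _sky_class(work["sky"])
    work["category"] = work["age"] + "/" + work["capture_window"] + "/" + work["skyclass"]
    work["fatclass"] = work["fat_score"].astype(int).map(lambda s: fat_class(s))

    out = {}
    for name, col in [
        ("category_x_activity", "category"),
        ("sky_x_activity", "skyclass"),
        ("period_x_activity", "capture_window"),
        ("fat_x_activity", "fatclass"),
    ]:
        table = pd.crosstab(work[col], work["active"])
        try:
            out[name] = cs.chisq_independence(table.to_numpy())
        except ValueError as err:
            out[name] = f"skipped ({err})"
    return out
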