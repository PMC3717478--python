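"""Daily physical-activity measures, affect composites and descriptives.

Activity labels collapse into behavior categories (lying/sitting ->
sedentary, standing -> inactive, walking -> MVPA, running -> very
vigorous).  The two PA measures are the fraction of wear time spent
active (MVPA + very vigorous) and the share of that active time spent
very vigorously.  Affect composites average each factor's three items
per occasion and then the occasion composites per day.  Descriptives
report grand mean, SD, the average intra-individual SD (ISD) and the
intraclass correlation (ICC) of each day-level variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CleanedEpochs
from .kinds import AFFECT_FACTORS, CATEGORY_OF, ActivityKind, BehaviorCategory

__all__ = [
    "DayRecord", "DailyAffect", "summarize_day", "affect_day_scores",
    "affect_day_table", "descriptives", "icc_empty_model", "icc_anova",
    "average_isd",
]


@dataclass(frozen=True)
class DayRecord:
    """Per-category durations and the two daily PA measures of one
    valid child-day."""

    child_id: str
    date: object
    sedentary_min: float
    inactive_min: float
    mvpa_min: float
    vigorous_min: float
    nonwear_min: float
    pa_fraction: float
    vigorous_share: float
    active_minutes: float
    zero_active_day: bool = False


@dataclass(frozen=True)
class DailyAffect:
    """Across-occasion mean composite per affect factor for one day."""

    child_id: str
    date: object
    pleasantness: float
    unpleasantness: float
    activation: float
    deactivation: float
    n_occasions_used: int


def summarize_day(epochs: CleanedEpochs, date=None) -> DayRecord:
    """Collapse one child-day's retained epochs into category durations
    and PA measures.

    ``pa_fraction`` is (MVPA + very vigorous) / wear time;
    ``vigorous_share`` is very vigorous / active time, 0 (flagged) on
    days without active epochs.
    """
    retained = epochs.retained
    labels = epochs.labels[retained]
    minutes = {cat: 0.0 for cat in BehaviorCategory}
    per_epoch_min = epochs.epoch_s / 60.0
    codes, counts = np.unique(labels, return_counts=True)
    for code, cnt in zip(codes, counts):
        minutes[CATEGORY_OF[ActivityKind(code)]] += cnt * per_epoch_min
    active = minutes[BehaviorCategory.mvpa] + minutes[BehaviorCategory.very_vigorous]
    wear = sum(minutes.values()) - minutes[BehaviorCategory.non_wear]
    if date is None:
        starts = epochs.epoch_starts()
        idx = np.flatnonzero(retained)
        date = (starts[idx[0]] if idx.size else epochs.start_time).date()
    return DayRecord(
        child_id=epochs.child_id,
        date=date,
        sedentary_min=minutes[BehaviorCategory.sedentary],
        inactive_min=minutes[BehaviorCategory.inactive],
        mvpa_min=minutes[BehaviorCategory.mvpa],
        vigorous_min=minutes[BehaviorCategory.very_vigorous],
        nonwear_min=minutes[BehaviorCategory.non_wear],
        pa_fraction=active / wear if wear > 0 else 0.0,
        vigorous_share=(minutes[BehaviorCategory.very_vigorous] / active) if active > 0 else 0.0,
        active_minutes=active,
        zero_active_day=active == 0,
    )


#: default item -> factor map for the 12-item instrument
DEFAULT_ITEM_MAP: dict[str, str] = {
    f"{factor}_{i}": factor for factor in AFFECT_FACTORS for i in (1, 2, 3)
}


def affect_day_scores(
    responses: pd.DataFrame,
    item_to_factor: dict[str, str] | None = None,
) -> DailyAffect:
    """Day-level affect composites for one child-day.

    ``responses`` has columns ``child_id, date, occasion, item_id,
    response`` (Likert 1-5) for a single child-day.  An occasion enters
    a factor's composite only when all three of its items are present;
    the day score is the mean over such occasions, and a factor with no
    complete occasion is reported as missing (NaN).
    """
    item_to_factor = item_to_factor or DEFAULT_ITEM_MAP
    df = responses.copy()
    if df["response"].lt(1).any() or df["response"].gt(5).any():
        raise ValueError("responses must be on the 1-5 scale")
    df["factor"] = df["item_id"].map(item_to_factor)
    if df["factor"].isna().any():
        bad = df.loc[df["factor"].isna(), "item_id"].unique().tolist()
        raise ValueError(f"unmapped item ids: {bad}")
    child = str(df["child_id"].iloc[0])
    date = df["date"].iloc[0]
    scores: dict[str, float] = {}
    n_used: list[int] = []
    for factor in AFFECT_FACTORS:
        sub = df[df["factor"] == factor]
        occ = sub.groupby("occasion")["response"].agg(["mean", "size"])
        complete = occ[occ["size"] == 3]["mean"]
        scores[factor] = float(complete.mean()) if len(complete) else float("nan")
        n_used.append(len(complete))
    return DailyAffect(
        child_id=child, date=date, n_occasions_used=max(n_used), **scores
    )


def affect_day_table(responses: pd.DataFrame, item_to_factor=None) -> pd.DataFrame:
    """Apply :func:`affect_day_scores` to every child-day in a long
    response table."""
    rows = []
    for (child, date), grp in responses.groupby(["child_id", "date"], sort=True):
        rows.append(affect_day_scores(grp, item_to_factor).__dict__)
    return pd.DataFrame(rows)


def average_isd(panel: pd.DataFrame, value: str, group: str = "child_id") -> float:
    """Mean over children of each child's own across-day SD."""
    sds = panel.groupby(group)[value].std(ddof=1)
    return float(sds.mean())


def icc_anova(panel: pd.DataFrame, value: str, group: str = "child_id") -> float:
    """One-way random-effects ICC by the method of moments (expected
    mean squares); negative between-variance estimates truncate to 0."""
    df = panel[[group, value]].dropna()
    groups = df.groupby(group)[value]
    k = groups.size()
    if len(k) < 2:
        return float("nan")
    grand = df[value].mean()
    n = len(df)
    ssb = float((k * (groups.mean() - grand) ** 2).sum())
    ssw = float(((df[value] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (len(k) - 1)
    msw = ssw / (n - len(k)) if n > len(k) else 0.0
    n0 = (n - float((k**2).sum()) / n) / (len(k) - 1)
    var_b = max(0.0, (msb - msw) / n0)
    total = var_b + msw
    return var_b / total if total > 0 else float("nan")


def icc_empty_model(panel: pd.DataFrame, value: str, group: str = "child_id") -> float:
    """ICC from the empty two-level model (random-intercept REML):
    between-child variance over total variance."""
    from .models import fit_hlm, build_design  # local import to avoid cycle

    df = panel[[group, value]].dropna()
    if df[group].nunique() < 2:
        return float("nan")
    design = build_design(
        df.assign(day_index=df.groupby(group).cumcount(), pa=0.0),
        outcome=value, pa_variable="pa", group=group, allow_constant_pa=True,
    )
    fit = fit_hlm(design, "empty")
    denom = fit.var_sigma0 + fit.var_epsilon
    return fit.var_sigma0 / denom if denom > 0 else float("nan")


def descriptives(
    panel: pd.DataFrame,
    variables: list[str],
    group: str = "child_id",
    icc_method: str = "empty_model",
) -> pd.DataFrame:
    """Descriptive table over a child-day panel: grand mean, SD, average
    ISD and ICC per variable.

    ICC comes from the empty two-level model by default
    (``icc_method="anova"`` selects the method-of-moments estimate);
    with a single child the ICC is undefined and reported as NaN.
    """
    icc_fun = {"empty_model": icc_empty_model, "anova": icc_anova}[icc_method]
    rows = []
    for v in variables:
        vals = panel[v].dropna()
        rows.append(
            {
                "variable": v,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "average_isd": average_isd(panel, v, group),
                "icc": icc_fun(panel, v, group),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
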