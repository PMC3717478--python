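"""End-to-end orchestration: raw signal -> features -> classified epochs
-> cleaned wear time -> daily summaries -> mixed models.

Processes one child-day at a time so a whole multi-week study never
holds more than one raw trace in memory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import ClassifierModel, ReferenceSet, predict_epochs, select_model, train_model
from .cleaning import DayWindow, build_day_windows, clean_day
from .frames import features_for_trace
from .kinds import AFFECT_FACTORS
from .simulate import StudyData, simulate_reference_session
from .summaries import affect_day_table, summarize_day

__all__ = ["train_reference_models", "run_study_pipeline", "merged_day_table"]


def train_reference_models(
    child_ids: list[str],
    participating: list[str] | None = None,
    seed: int = 0,
    **svm_kwargs,
) -> tuple[dict[str, ClassifierModel], ClassifierModel]:
    """Simulate a reference session per participating child and train
    the individual models plus the pooled general model."""
    participating = list(child_ids) if participating is None else list(participating)
    refsets, individual = {}, {}
    for i, child in enumerate(participating):
        trace, labels = simulate_reference_session(child, seed=seed + 7919 * (i + 1))
        refset = ReferenceSet.from_session(features_for_trace(trace), labels)
        refsets[child] = refset
        individual[child] = train_model(refset, **svm_kwargs)
    general = train_model(ReferenceSet.pooled(list(refsets.values())), **svm_kwargs)
    return individual, general


def run_study_pipeline(
    study: StudyData,
    individual_models: dict[str, ClassifierModel],
    general_model: ClassifierModel,
    window_min: float = 60.0,
    tolerance_min: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full chain on every child-day of a simulated study.

    Returns ``(day_table, wear_table)``: the day table holds one row per
    *valid* child-day with category durations, PA measures and the four
    affect composites; the wear table records wear hours and validity of
    every child-day.
    """
    windows = {
        (w.child_id, pd.Timestamp(w.date)): w
        for w in build_day_windows(study.sleep_reports)
    }
    day_rows, wear_rows = [], []
    for (child, date) in study.schedules:
        trace = study.trace(child, date)
        feats = features_for_trace(trace)
        model = select_model(child, individual_models, general_model)
        epochs = predict_epochs(model, feats)
        window = windows.get((child, pd.Timestamp(date)))
        cleaned, wear = clean_day(epochs, window, window_min, tolerance_min)
        wear_rows.append(
            {
                "child_id": child,
                "date": pd.Timestamp(date).date(),
                "wear_hours": wear.wear_hours,
                "valid": wear.is_valid_day,
            }
        )
        if wear.is_valid_day:
            rec = summarize_day(cleaned, date=pd.Timestamp(date).date())
            day_rows.append(rec.__dict__)
    wear_table = pd.DataFrame(wear_rows)
    day_table = pd.DataFrame(day_rows)
    affect = affect_day_table(study.affect_responses)
    return merged_day_table(day_table, affect), wear_table


def merged_day_table(day_table: pd.DataFrame, affect: pd.DataFrame) -> pd.DataFrame:
    """Join PA day records with affect day scores and add each child's
    day index (0 at the child's first valid day)."""
    if day_table.empty:
        return day_table
    day_table = day_table.copy()
    affect = affect.copy()
    for df in (day_table, affect):
        df["date"] = pd.to_datetime(df["date"]).dt.date
    merged = day_table.merge(
        affect[["child_id", "date", *AFFECT_FACTORS, "n_occasions_used"]],
        on=["child_id", "date"],
        how="left",
    )
    merged = merged.sort_values(["child_id", "date"]).reset_index(drop=True)
    first = merged.groupby("child_id")["date"].transform("min")
    merged["day_index"] = [
        (d - f).days for d, f in zip(merged["date"], first)
    ]
    return merged
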