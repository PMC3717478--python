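"""Monte-Carlo calibration experiments for the whole chain.

These are the package's own checks of its statistical machinery:
classifier separability on held-out reference data, parameter recovery
and type-I error of the mixed models, and the end-to-end null-world
behavior of the pipeline.  Both the test suite and the reproduction
script run them; sizes are chosen to finish in minutes on one CPU.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .classify import ReferenceSet, predict_epochs, train_model
from .frames import features_for_trace
from .models import build_design, fit_hlm
from .pipeline import run_study_pipeline, train_reference_models
from .simulate import (
    DEFAULT_SIGNAL_PARAMS,
    AffectDGPParams,
    SignalParams,
    simulate_affect_panel,
    simulate_reference_session,
    simulate_study,
)

__all__ = [
    "zero_noise_signal_params",
    "classifier_separability",
    "parameter_recovery",
    "type1_error_rate",
    "null_world_pipeline",
    "RECOVERY_DGP",
]


def zero_noise_signal_params() -> dict:
    """Default signal parameters with sensor noise removed: the regime
    in which the seven classes have disjoint feature supports."""
    return {
        kind: SignalParams(
            p.gravity_unit_vector, p.gait_frequency, p.gait_amplitude,
            0.0, p.table_position_index,
        )
        for kind, p in DEFAULT_SIGNAL_PARAMS.items()
    }


def classifier_separability(n_children: int = 5, seed: int = 0) -> dict:
    """Held-out accuracy in the zero-noise regime.

    Trains an individual model per simulated child and the pooled
    general model on one reference session each, then scores both on a
    fresh session per child.  Returns per-model accuracies.
    """
    params = zero_noise_signal_params()
    refsets, tests = [], []
    for i in range(n_children):
        tr, lab = simulate_reference_session(
            f"c{i}", params_per_kind=params, seed=seed + 2 * i
        )
        refsets.append(ReferenceSet.from_session(features_for_trace(tr), lab))
        tr2, lab2 = simulate_reference_session(
            f"c{i}", params_per_kind=params, seed=seed + 2 * i + 1
        )
        tests.append(ReferenceSet.from_session(features_for_trace(tr2), lab2))
    individual_acc = []
    for ref, test in zip(refsets, tests):
        model = train_model(ref)
        individual_acc.append(float((model.predict(test.features) == test.labels).mean()))
    general = train_model(ReferenceSet.pooled(refsets))
    general_acc = [
        float((general.predict(t.features) == t.labels).mean()) for t in tests
    ]
    return {
        "individual_accuracy": individual_acc,
        "general_accuracy": float(np.mean(general_acc)),
        "general_accuracy_min": float(np.min(general_acc)),
    }


#: interior-valued generating parameters for the recovery study.  Every
#: variance sits away from its boundary so the mean-estimate-vs-truth
#: comparison is well posed (at a boundary the non-negative estimator is
#: biased upward by construction; boundary behavior is checked separately).
RECOVERY_DGP = AffectDGPParams(
    gamma30=0.3, var_sigma3=0.25, cov_sigma0_sigma1=0.005
)

RECOVERY_PARAM_NAMES = (
    "gamma00", "gamma10", "gamma20", "gamma30",
    "var_sigma0", "var_sigma1", "var_sigma3", "var_epsilon",
)


def parameter_recovery(
    n_reps: int = 100,
    n_children: int = 100,
    n_days: int = 20,
    seed: int = 0,
    dgp: AffectDGPParams = RECOVERY_DGP,
    pa_within_sd: float = 0.15,
) -> pd.DataFrame:
    """Replicate the data-generating process and refit the final model.

    Returns one row per parameter with the truth, the Monte-Carlo mean
    estimate, its MC standard error, and the z-score of the difference.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            panel, _ = simulate_affect_panel(
                dgp, n_children, n_days, seed=seed + r, pa_within_sd=pa_within_sd
            )
            design = build_design(
                panel.assign(day_index=panel["day"]), "affect", "pa"
            )
            fit = fit_hlm(design, "fixed_and_random")
            fe = fit.fixed["estimate"]
            rows.append([
                fe["intercept"], fe["trend"], fe["average_activity"],
                fe["daily_activity"], fit.var_sigma0, fit.var_sigma1,
                fit.var_sigma3, fit.var_epsilon,
            ])
    est = np.array(rows)
    truth = [getattr(dgp, n) for n in RECOVERY_PARAM_NAMES]
    mean = est.mean(axis=0)
    mcse = est.std(axis=0, ddof=1) / np.sqrt(n_reps)
    return pd.DataFrame({
        "parameter": RECOVERY_PARAM_NAMES,
        "truth": truth,
        "mean_estimate": mean,
        "mc_se": mcse,
        "z": (mean - truth) / mcse,
    }).set_index("parameter")


def type1_error_rate(
    n_reps: int = 400,
    n_children: int = 100,
    n_days: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the daily-activity Wald test under the null
    (no within-person effect, no slope heterogeneity)."""
    dgp = AffectDGPParams(gamma30=0.0, var_sigma3=0.0)
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            panel, _ = simulate_affect_panel(dgp, n_children, n_days, seed=seed + r)
            design = build_design(
                panel.assign(day_index=panel["day"]), "affect", "pa"
            )
            fit = fit_hlm(design, "fixed_only")
            rejections += fit.fixed.loc["daily_activity", "p"] < alpha
    return rejections / n_reps


def null_world_pipeline(
    seed: int,
    n_children: int = 10,
    n_days: int = 10,
    outcome: str = "pleasantness",
    pa_variable: str = "pa_fraction",
    wake_hour: float = 7.0,
    bed_hour: float = 14.5,
) -> dict:
    """Full raw-signal pipeline on one simulated null world (no daily
    activity -> affect effect), returning the daily-activity Wald p-value
    of the final model plus bookkeeping.

    Days are shortened (default ~7.5 h wake windows, still above the 6 h
    valid-day bound) so multi-seed runs stay cheap; every stage of the
    chain is exercised regardless.
    """
    dgp = AffectDGPParams(gamma30=0.0, var_sigma3=0.0)
    study = simulate_study(
        n_children, n_days, seed=seed, dgp=dgp,
        wake_hour=wake_hour, bed_hour=bed_hour, window_jitter_min=10,
    )
    # most children attend the reference measurement; the rest use the
    # pooled general model
    n_ref = max(2, int(round(0.7 * n_children)))
    individual, general = train_reference_models(
        study.children, participating=study.children[:n_ref], seed=seed + 131
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        day_table, wear = run_study_pipeline(study, individual, general)
        design = build_design(day_table, outcome, pa_variable)
        fit = fit_hlm(design, "fixed_and_random")
    truth = study.day_truth.merge(
        day_table, on=["child_id", "date"], suffixes=("_true", "")
    )
    pa_err = float(np.abs(truth["pa_fraction"] - truth["pa_fraction_true"]).mean())
    return {
        "p_daily_activity": float(fit.fixed.loc["daily_activity", "p"]),
        "gamma30_hat": float(fit.fixed.loc["daily_activity", "estimate"]),
        "n_valid_days": int(wear["valid"].sum()),
        "n_days_total": len(wear),
        "mean_abs_pa_error": pa_err,
    }
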