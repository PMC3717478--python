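"""Synthetic data generator for the whole measurement chain.

Emulates the four inputs of a waist-worn-accelerometer ambulatory
assessment study of elementary-school children:

* raw 30 Hz triaxial acceleration traces for seven epoch classes — six
  reference activities (lying, sitting, standing, slow/fast walking,
  running) plus the device-off state (device lying on a table in one of
  three positions);
* labeled reference sessions following a pre-defined activity protocol;
* morning sleep diaries (bed time of the previous night, wake time);
* 12-item Likert (1-5) affect self-reports at four occasions per day,
  three items per factor (pleasantness, unpleasantness, activation,
  deactivation).

The signal model is deliberately simple: postures differ by mean gravity
orientation, locomotion adds a gait sinusoid on the vertical axis (half
amplitude, quarter-period shifted, on the anterior axis), the device at
rest shows a fixed orientation with minimal sensor noise.  Daily affect
follows a two-level linear model: person-specific intercept, linear time
trend and daily-activity slope (random effects), plus fixed effects of
the person's average activity and the daily deviation from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_RATE_HZ,
    DEVICE_RANGE_G,
    EPOCH_SECONDS,
    AccelTrace,
    LabeledEpochs,
)
from .kinds import AFFECT_FACTORS, ALL_KINDS, ActivityKind

__all__ = [
    "SignalParams",
    "AffectDGPParams",
    "StudyData",
    "DEFAULT_SIGNAL_PARAMS",
    "DEFAULT_FACTOR_DGPS",
    "TABLE_ORIENTATIONS",
    "simulate_activity_trace",
    "simulate_reference_session",
    "simulate_affect_panel",
    "simulate_study",
    "write_study_csv",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: The three resting orientations of a device lying on a flat surface
#: (face up, on its side, face down), indexed 1..3.
TABLE_ORIENTATIONS: dict[int, np.ndarray] = {
    1: np.array([0.0, 0.0, 1.0]),
    2: np.array([1.0, 0.0, 0.0]),
    3: np.array([0.0, 0.0, -1.0]),
}


@dataclass(frozen=True)
class SignalParams:
    """Signal-model parameters for one activity class.

    ``gravity_unit_vector`` is the mean orientation (unit norm, axes
    x = medio-lateral, y = vertical, z = anterior-posterior);
    ``gait_frequency`` (Hz) and ``gait_amplitude`` (g) shape the
    locomotion sinusoid and are zero for postures and non-wear;
    ``noise_sd`` (g) is white sensor/movement noise;
    ``table_position_index`` selects the resting orientation (non-wear
    only).
    """

    gravity_unit_vector: np.ndarray
    gait_frequency: float = 0.0
    gait_amplitude: float = 0.0
    noise_sd: float = 0.03
    table_position_index: int = 1

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_unit_vector, dtype=float)
        object.__setattr__(self, "gravity_unit_vector", g)
        if abs(np.linalg.norm(g) - 1.0) > 1e-9:
            raise ValueError("gravity_unit_vector must have unit norm")
        if self.gait_frequency < 0 or self.noise_sd < 0:
            raise ValueError("gait_frequency and noise_sd must be >= 0")
        if self.gait_frequency == 0 and self.gait_amplitude != 0:
            raise ValueError("gait_amplitude must be 0 when gait_frequency is 0")
        if self.table_position_index not in (1, 2, 3):
            raise ValueError("table_position_index must be 1, 2 or 3")


#: Default per-class signal parameters.  Orientations are distinct across
#: classes and the gait sinusoids grow in frequency and amplitude from slow
#: walking to running, so the classes are separable at noise_sd <= 0.05 g.
DEFAULT_SIGNAL_PARAMS: dict[ActivityKind, SignalParams] = {
    ActivityKind.lying: SignalParams(_unit([0.15, 0.20, 0.97]), noise_sd=0.02),
    ActivityKind.sitting: SignalParams(_unit([0.20, 0.95, 0.25]), noise_sd=0.025),
    ActivityKind.standing: SignalParams(np.array([0.0, 1.0, 0.0]), noise_sd=0.03),
    ActivityKind.walk_slow: SignalParams(
        np.array([0.0, 1.0, 0.0]), gait_frequency=1.5, gait_amplitude=0.25, noise_sd=0.05
    ),
    ActivityKind.walk_fast: SignalParams(
        np.array([0.0, 1.0, 0.0]), gait_frequency=2.0, gait_amplitude=0.45, noise_sd=0.05
    ),
    ActivityKind.running: SignalParams(
        np.array([0.0, 1.0, 0.0]), gait_frequency=2.8, gait_amplitude=0.80, noise_sd=0.05
    ),
    ActivityKind.non_wear: SignalParams(
        TABLE_ORIENTATIONS[1], noise_sd=0.002, table_position_index=1
    ),
}


def _synth_samples(
    kind: ActivityKind,
    n: int,
    params: SignalParams,
    rng: np.random.Generator,
    rate: float,
) -> np.ndarray:
    """Generate n raw samples for one activity bout; clipped to the
    device range."""
    if kind == ActivityKind.non_wear:
        base = TABLE_ORIENTATIONS[params.table_position_index]
    else:
        base = params.gravity_unit_vector
    out = np.tile(base, (n, 1))
    if params.gait_frequency > 0:
        t = np.arange(n) / rate
        phase = 2.0 * np.pi * params.gait_frequency * t
        out[:, 1] += params.gait_amplitude * np.sin(phase)
        # anterior axis carries half the vertical excursion, quarter-period shifted
        out[:, 2] += 0.5 * params.gait_amplitude * np.sin(phase + np.pi / 2.0)
    if params.noise_sd > 0:
        out += rng.normal(0.0, params.noise_sd, size=(n, 3))
    np.clip(out, -DEVICE_RANGE_G, DEVICE_RANGE_G, out=out)
    return out


def simulate_activity_trace(
    kind: ActivityKind,
    duration_s: float,
    params: SignalParams | None = None,
    seed: int = 0,
    rate: float = DEFAULT_RATE_HZ,
    child_id: str = "sim",
    start_time="2013-04-05 10:00:00",
) -> AccelTrace:
    """Simulate a single-activity trace of ``duration_s`` seconds."""
    kind = ActivityKind(kind)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = duration_s * rate
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration times rate must be an integer sample count")
    if params is None:
        params = DEFAULT_SIGNAL_PARAMS[kind]
    rng = np.random.default_rng(seed)
    samples = _synth_samples(kind, int(round(n)), params, rng, rate)
    return AccelTrace(child_id=child_id, start_time=start_time, samples=samples, rate=rate)


DEFAULT_PROTOCOL: tuple[tuple[ActivityKind, float], ...] = tuple(
    (k, 60.0) for k in ALL_KINDS
)


def simulate_reference_session(
    child_id: str,
    protocol=DEFAULT_PROTOCOL,
    params_per_kind: dict[ActivityKind, SignalParams] | None = None,
    seed: int = 0,
    rate: float = DEFAULT_RATE_HZ,
    start_time="2013-04-05 10:00:00",
) -> tuple[AccelTrace, LabeledEpochs]:
    """Simulate one child's labeled reference session.

    The protocol must cover all seven classes (six activities plus
    non-wear) and every bout duration must be a multiple of the 2.5 s
    epoch length so that no epoch straddles two activities.
    """
    params_per_kind = {**DEFAULT_SIGNAL_PARAMS, **(params_per_kind or {})}
    kinds_present = {ActivityKind(k) for k, _ in protocol}
    missing = set(ALL_KINDS) - kinds_present
    if missing:
        raise ValueError(f"protocol missing labels: {sorted(m.name for m in missing)}")
    rng = np.random.default_rng(seed)
    chunks, labels = [], []
    for kind, dur in protocol:
        kind = ActivityKind(kind)
        n_ep = dur / EPOCH_SECONDS
        if abs(n_ep - round(n_ep)) > 1e-9:
            raise ValueError(
                f"duration {dur} s for {kind.name} is not a multiple of {EPOCH_SECONDS} s"
            )
        n = int(round(dur * rate))
        chunks.append(_synth_samples(kind, n, params_per_kind[kind], rng, rate))
        labels.extend([kind.value] * int(round(n_ep)))
    trace = AccelTrace(child_id, start_time, np.vstack(chunks), rate=rate)
    epochs = LabeledEpochs(child_id, start_time, np.array(labels, dtype=np.int8))
    return trace, epochs


# ---------------------------------------------------------------------------
# Affect data-generating process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffectDGPParams:
    """Parameters of the two-level affect model used for generation.

    Fixed effects (affect-scale units): ``gamma00`` intercept,
    ``gamma10`` linear trend per day, ``gamma20`` between-person average
    activity, ``gamma30`` within-person daily activity deviation.
    Random effects: intercept variance ``var_sigma0``, trend variance
    ``var_sigma1``, daily-activity slope variance ``var_sigma3``, and the
    intercept-trend covariance ``cov_sigma0_sigma1``; ``var_epsilon`` is
    the day-level residual variance.
    """

    gamma00: float = 3.982
    gamma10: float = -0.012
    gamma20: float = 0.970
    gamma30: float = 0.054
    var_sigma0: float = 0.380
    var_sigma1: float = 0.0009
    var_sigma3: float = 0.0
    cov_sigma0_sigma1: float = 0.0
    var_epsilon: float = 0.297

    def validate(self) -> None:
        for name in ("var_sigma0", "var_sigma1", "var_sigma3", "var_epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        cov = np.array(
            [
                [self.var_sigma0, self.cov_sigma0_sigma1],
                [self.cov_sigma0_sigma1, self.var_sigma1],
            ]
        )
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("intercept/trend covariance matrix is not PSD")


#: Per-factor generating parameters.  Positive factors sit high on the 1-5
#: scale with a small negative drift; negative factors sit low.  Units are
#: Likert points; activity slopes are per unit activity fraction.
DEFAULT_FACTOR_DGPS: dict[str, AffectDGPParams] = {
    "pleasantness": AffectDGPParams(),
    "unpleasantness": AffectDGPParams(
        gamma00=1.530, gamma10=0.008, gamma20=-0.855, gamma30=-0.231,
        var_sigma0=0.233, var_sigma1=0.0007, var_sigma3=0.229, var_epsilon=0.157,
    ),
    "activation": AffectDGPParams(
        gamma00=3.977, gamma10=-0.018, gamma20=-0.552, gamma30=0.112,
        var_sigma0=0.826, var_sigma1=0.001, var_sigma3=0.0, var_epsilon=0.274,
    ),
    "deactivation": AffectDGPParams(
        gamma00=1.738, gamma10=-0.002, gamma20=-0.640, gamma30=-0.258,
        var_sigma0=0.321, var_sigma1=0.0008, var_sigma3=0.054, var_epsilon=0.214,
    ),
}


def _truncnorm(rng, mu, sd, lo, hi, size):
    from scipy import stats

    mu = np.asarray(mu, dtype=float)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _draw_random_effects(dgp: AffectDGPParams, n: int, rng: np.random.Generator):
    cov = np.array(
        [
            [dgp.var_sigma0, dgp.cov_sigma0_sigma1],
            [dgp.cov_sigma0_sigma1, dgp.var_sigma1],
        ]
    )
    s01 = rng.multivariate_normal(np.zeros(2), cov, size=n, method="svd")
    s3 = rng.normal(0.0, np.sqrt(dgp.var_sigma3), size=n)
    return s01[:, 0], s01[:, 1], s3


def _affect_day_means(
    dgp: AffectDGPParams,
    pa: np.ndarray,  # (n_children, n_days) daily activity fraction
    rng: np.random.Generator,
):
    """Latent day-level affect from the two-level model.

    The within-person covariate is each day's deviation from the child's
    own study average; the average itself enters with a fixed slope.
    Returns (day means, (sigma0, sigma1, sigma3))."""
    n_children, n_days = pa.shape
    s0, s1, s3 = _draw_random_effects(dgp, n_children, rng)
    trend = np.arange(n_days)[None, :]
    pa_between = pa.mean(axis=1, keepdims=True)
    pa_within = pa - pa_between
    mu = (
        (dgp.gamma00 + s0)[:, None]
        + (dgp.gamma10 + s1)[:, None] * trend
        + dgp.gamma20 * pa_between
        + (dgp.gamma30 + s3)[:, None] * pa_within
    )
    eps = rng.normal(0.0, np.sqrt(dgp.var_epsilon), size=mu.shape)
    return mu + eps, (s0, s1, s3)


def simulate_affect_panel(
    dgp: AffectDGPParams,
    n_children: int,
    n_days: int,
    seed: int = 0,
    pa_between_mean: float = 0.15,
    pa_between_sd: float = 0.05,
    pa_within_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day-level panel straight from the affect model, bypassing the
    signal chain (for calibration and parameter-recovery work).

    Returns ``(panel, effects)``: the panel has one row per child-day
    with the daily activity fraction and the continuous affect score;
    ``effects`` holds each child's random-effect draws.
    """
    if n_children < 2 or n_days < 2:
        raise ValueError("need at least 2 children and 2 days")
    dgp.validate()
    rng = np.random.default_rng(seed)
    # activity fractions live in (0, 1); truncated normals avoid the
    # atom at the bound a hard clip would create
    pa_i = _truncnorm(rng, pa_between_mean, pa_between_sd, 0.02, 0.90,
                      (n_children, 1))
    pa = _truncnorm(rng, pa_i, pa_within_sd, 0.005, 0.95, (n_children, n_days))
    y, (s0, s1, s3) = _affect_day_means(dgp, pa, rng)
    child_ids = [f"c{i:04d}" for i in range(n_children)]
    panel = pd.DataFrame(
        {
            "child_id": np.repeat(child_ids, n_days),
            "day": np.tile(np.arange(n_days), n_children),
            "pa": pa.ravel(),
            "affect": y.ravel(),
        }
    )
    effects = pd.DataFrame(
        {"child_id": child_ids, "sigma0": s0, "sigma1": s1, "sigma3": s3}
    )
    return panel, effects


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

# target time shares of the wake window per class and mean bout lengths
# (minutes); active share ~15% of wear time with ~21% of it very vigorous,
# plus ~8% of the window as device-off episodes
_BOUT_SHARE = {
    ActivityKind.sitting: 0.435,
    ActivityKind.lying: 0.046,
    ActivityKind.standing: 0.305,
    ActivityKind.walk_slow: 0.074,
    ActivityKind.walk_fast: 0.037,
    ActivityKind.running: 0.029,
    ActivityKind.non_wear: 0.074,
}
_BOUT_MEAN_MIN = {
    ActivityKind.sitting: 12.0,
    ActivityKind.lying: 15.0,
    ActivityKind.standing: 4.0,
    ActivityKind.walk_slow: 3.0,
    ActivityKind.walk_fast: 2.0,
    ActivityKind.running: 1.0,
    ActivityKind.non_wear: 45.0,
}
_ACTIVE = (ActivityKind.walk_slow, ActivityKind.walk_fast, ActivityKind.running)


def default_schedule_generator(
    rng: np.random.Generator, n_epochs: int, activity_factor: float = 1.0
) -> np.ndarray:
    """Fill a wake window with activity bouts.

    Bout classes are drawn with probabilities proportional to target
    time-share over mean bout length; bout lengths are exponential
    (minimum one epoch).  ``activity_factor`` scales the draw rate of the
    three active classes, creating stable between-child and day-to-day
    differences in activity.
    """
    kinds = list(_BOUT_SHARE)
    w = np.array([_BOUT_SHARE[k] / _BOUT_MEAN_MIN[k] for k in kinds])
    active_idx = [kinds.index(k) for k in _ACTIVE]
    w[active_idx] *= activity_factor
    w = w / w.sum()
    epochs_per_min = 60.0 / EPOCH_SECONDS
    out = np.empty(n_epochs, dtype=np.int8)
    pos = 0
    while pos < n_epochs:
        k = kinds[rng.choice(len(kinds), p=w)]
        n_ep = max(1, int(round(rng.exponential(_BOUT_MEAN_MIN[k]) * epochs_per_min)))
        n_ep = min(n_ep, n_epochs - pos)
        out[pos : pos + n_ep] = k.value
        pos += n_ep
    return out


@dataclass
class StudyData:
    """Container for one simulated study.

    Raw traces are not stored; :meth:`trace` regenerates the trace of any
    child-day deterministically from the per-day seed, so a whole study
    can be processed one day at a time.
    """

    children: list[str]
    windows: pd.DataFrame          # child_id, date, wake_time, bed_time (truth)
    sleep_reports: pd.DataFrame    # diary rows: child_id, date, bed_time, wake_time
    day_truth: pd.DataFrame        # per child-day ground truth
    affect_responses: pd.DataFrame  # child_id, date, occasion, item_id, response
    schedules: dict = field(repr=False, default_factory=dict)
    _trace_seeds: dict = field(repr=False, default_factory=dict)
    rate: float = DEFAULT_RATE_HZ
    margin_epochs: int = 360  # 15 min of device-off padding on each side

    def schedule(self, child_id: str, date) -> LabeledEpochs:
        """Ground-truth epoch labels for one child-day (wake window only)."""
        start, labels = self.schedules[(child_id, pd.Timestamp(date))]
        return LabeledEpochs(child_id, start, labels)

    def trace(self, child_id: str, date) -> AccelTrace:
        """Regenerate the raw 30 Hz trace of one child-day, padded with
        15 min of device-off signal on each side of the wake window."""
        key = (child_id, pd.Timestamp(date))
        start, labels = self.schedules[key]
        rng = np.random.default_rng(self._trace_seeds[key])
        pad = np.full(self.margin_epochs, ActivityKind.non_wear.value, dtype=np.int8)
        full = np.concatenate([pad, labels, pad])
        t0 = start - pd.to_timedelta(self.margin_epochs * EPOCH_SECONDS, unit="s")
        spf = int(round(EPOCH_SECONDS * self.rate))
        chunks = []
        # synthesize per run of identical labels, varying the table
        # orientation per device-off episode
        boundaries = np.flatnonzero(np.diff(full)) + 1
        for seg in np.split(full, boundaries):
            kind = ActivityKind(seg[0])
            params = DEFAULT_SIGNAL_PARAMS[kind]
            if kind == ActivityKind.non_wear:
                params = replace(
                    params, table_position_index=int(rng.integers(1, 4))
                )
            chunks.append(_synth_samples(kind, seg.size * spf, params, rng, self.rate))
        return AccelTrace(child_id, t0, np.vstack(chunks), rate=self.rate)


def simulate_study(
    n_children: int,
    n_days: int,
    seed: int = 0,
    dgp: AffectDGPParams | dict[str, AffectDGPParams] | None = None,
    schedule_generator=default_schedule_generator,
    wake_hour: float = 7.0,
    bed_hour: float = 21.0,
    window_jitter_min: float = 30.0,
    start_date="2013-04-08",
    item_noise_sd: float = 0.25,
    occasion_noise_sd: float = 0.2,
) -> StudyData:
    """Simulate a full study: schedules, diaries, affect responses and
    ground-truth day tables for ``n_children`` x ``n_days``.

    ``dgp`` may be one :class:`AffectDGPParams` (applied to every affect
    factor) or a dict keyed by factor name; default: per-factor defaults.
    Wake windows are drawn as ``wake_hour`` +/- ``window_jitter_min`` to
    ``bed_hour`` +/- ``window_jitter_min``.
    """
    if n_children < 2 or n_days < 2:
        raise ValueError("need at least 2 children and 2 days")
    if dgp is None:
        factor_dgps = dict(DEFAULT_FACTOR_DGPS)
    elif isinstance(dgp, AffectDGPParams):
        factor_dgps = {f: dgp for f in AFFECT_FACTORS}
    else:
        factor_dgps = dict(dgp)
    for p in factor_dgps.values():
        p.validate()

    root = np.random.default_rng(np.random.SeedSequence(seed))
    start_date = pd.Timestamp(start_date).normalize()
    dates = [start_date + pd.Timedelta(days=t) for t in range(n_days)]
    children = [f"c{i:03d}" for i in range(n_children)]

    schedules: dict = {}
    trace_seeds: dict = {}
    win_rows = []
    pa = np.zeros((n_children, n_days))
    vig = np.zeros((n_children, n_days))
    wear_hours = np.zeros((n_children, n_days))

    child_activity = np.exp(root.normal(0.0, 0.35, size=n_children))
    for i, child in enumerate(children):
        crng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + i]))
        for t, date in enumerate(dates):
            jit = crng.uniform(-window_jitter_min, window_jitter_min, size=2)
            wake = date + pd.Timedelta(minutes=wake_hour * 60 + jit[0])
            bed = date + pd.Timedelta(minutes=bed_hour * 60 + jit[1])
            # snap to the 2.5 s epoch grid
            wake = wake.floor("2500ms")
            bed = bed.floor("2500ms")
            n_ep = int(round((bed - wake).total_seconds() / EPOCH_SECONDS))
            day_factor = float(np.exp(crng.normal(0.0, 0.25)))
            labels = schedule_generator(crng, n_ep, child_activity[i] * day_factor)
            schedules[(child, date)] = (wake, labels)
            trace_seeds[(child, date)] = int(
                np.random.SeedSequence([seed, 1000 + i, t]).generate_state(1)[0]
                % (2**31)
            )
            worn = labels != ActivityKind.non_wear.value
            active = np.isin(labels, [k.value for k in _ACTIVE])
            n_worn = int(worn.sum())
            pa[i, t] = active.sum() / n_worn if n_worn else 0.0
            running = labels == ActivityKind.running.value
            n_active = int(active.sum())
            vig[i, t] = running.sum() / n_active if n_active else 0.0
            wear_hours[i, t] = n_worn * EPOCH_SECONDS / 3600.0
            win_rows.append((child, date.date(), wake, bed))

    windows = pd.DataFrame(
        win_rows, columns=["child_id", "date", "wake_time", "bed_time"]
    )
    # diary semantics: the report of date d carries the bed time of the
    # previous evening and the wake time of d's morning
    diary = windows.copy()
    diary["bed_prev"] = diary.groupby("child_id")["bed_time"].shift(1)
    first = diary["bed_prev"].isna()
    diary.loc[first, "bed_prev"] = (
        diary.loc[first, "bed_time"] - pd.Timedelta(days=1)
    )
    sleep_reports = diary[["child_id", "date", "bed_prev", "wake_time"]].rename(
        columns={"bed_prev": "bed_time"}
    )

    # affect: latent day means per factor, then items
    arng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    truth = pd.DataFrame(
        {
            "child_id": np.repeat(children, n_days),
            "date": [d.date() for d in dates] * n_children,
            "day_index": np.tile(np.arange(n_days), n_children),
            "pa_fraction_true": pa.ravel(),
            "vigorous_share_true": vig.ravel(),
            "wear_hours_true": wear_hours.ravel(),
        }
    )
    resp_frames = []
    for factor in AFFECT_FACTORS:
        y, _ = _affect_day_means(factor_dgps[factor], pa, arng)
        truth[f"{factor}_latent"] = y.ravel()
        occ = y[:, :, None] + arng.normal(0.0, occasion_noise_sd, size=(*y.shape, 4))
        items = occ[..., None] + arng.normal(
            0.0, item_noise_sd, size=(*occ.shape, 3)
        )
        resp = np.clip(np.rint(items), 1, 5).astype(int)
        idx = pd.MultiIndex.from_product(
            [children, [d.date() for d in dates], [1, 2, 3, 4], [1, 2, 3]],
            names=["child_id", "date", "occasion", "item_no"],
        )
        df = pd.DataFrame({"response": resp.ravel()}, index=idx).reset_index()
        df["item_id"] = factor + "_" + df.pop("item_no").astype(str)
        resp_frames.append(df[["child_id", "date", "occasion", "item_id", "response"]])
    affect_responses = (
        pd.concat(resp_frames)
        .sort_values(["child_id", "date", "occasion", "item_id"])
        .reset_index(drop=True)
    )

    return StudyData(
        children=children,
        windows=windows,
        sleep_reports=sleep_reports,
        day_truth=truth,
        affect_responses=affect_responses,
        schedules=schedules,
        _trace_seeds=trace_seeds,
    )


def write_study_csv(study: StudyData, outdir, include_traces: bool = False) -> None:
    """Write diaries, affect responses and ground truth (optionally raw
    per-day trace CSVs) to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.sleep_reports.to_csv(out / "sleep_diary.csv", index=False)
    study.affect_responses.to_csv(out / "affect_responses.csv", index=False)
    study.day_truth.to_csv(out / "day_truth.csv", index=False)
    study.windows.to_csv(out / "wake_windows.csv", index=False)
    if include_traces:
        (out / "raw").mkdir(exist_ok=True)
        for child, date in study.schedules:
            study.trace(child, date).to_csv(
                out / "raw" / f"{child}_{pd.Timestamp(date).date()}.csv"
            )
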