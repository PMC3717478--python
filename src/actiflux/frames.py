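"""Non-overlapping 2.5 s frame segmentation and the 12 per-frame key-values.

Each frame of 75 samples (30 Hz x 2.5 s) is summarized by 12 features:
per-axis mean and variance, the three pairwise inter-axis correlations,
and per-axis spectral energy.  The short frame length suits children's
movement, which comes in short, irregular bouts.

Conventions
-----------
* Variance uses the population (1/n) normalizer.
* Correlation of a zero-variance axis is defined as 0 (device-off frames
  are near-constant and the classifier needs a finite value).
* Energy is the sum of squared discrete-Fourier magnitudes excluding the
  zero-frequency (gravity) component, normalized so that a sinusoid of
  amplitude ``a`` spanning whole cycles has energy ``a**2 / 2``; by
  Parseval's identity this equals the frame's mean squared deviation
  from its mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EPOCH_SECONDS, AccelTrace

__all__ = ["FEATURE_COLUMNS", "segment_frames", "compute_features", "features_for_trace",
           "write_feature_csv", "read_feature_csv"]

FEATURE_COLUMNS: tuple[str, ...] = (
    "mean_x", "mean_y", "mean_z",
    "var_x", "var_y", "var_z",
    "corr_xy", "corr_xz", "corr_yz",
    "energy_x", "energy_y", "energy_z",
)


def segment_frames(trace: AccelTrace, frame_length_s: float = EPOCH_SECONDS) -> np.ndarray:
    """Cut a trace into complete non-overlapping frames.

    Returns an array of shape ``(n_frames, samples_per_frame, 3)``; a
    trailing partial frame is discarded.  The sampling rate times the
    frame length must be an integer.
    """
    spf = trace.rate * frame_length_s
    if abs(spf - round(spf)) > 1e-9:
        raise ValueError(
            f"rate {trace.rate} Hz x frame length {frame_length_s} s "
            "is not an integer number of samples"
        )
    spf = int(round(spf))
    n_frames = trace.n_samples // spf
    return trace.samples[: n_frames * spf].reshape(n_frames, spf, 3)


def _features_from_array(frames: np.ndarray) -> np.ndarray:
    """Vectorized 12-feature computation for ``(n, spf, 3)`` frames."""
    n, spf, _ = frames.shape
    means = frames.mean(axis=1)                        # (n, 3)
    dev = frames - means[:, None, :]
    var = (dev**2).mean(axis=1)                        # population variance
    # an axis is "constant" when its variance is at rounding level for
    # its magnitude; its correlations are 0 by convention
    eps = 1e-13 * (1.0 + means**2)
    sd = np.where(var > eps, np.sqrt(var), 0.0)
    # pairwise correlations with the zero-variance convention
    cov_xy = (dev[:, :, 0] * dev[:, :, 1]).mean(axis=1)
    cov_xz = (dev[:, :, 0] * dev[:, :, 2]).mean(axis=1)
    cov_yz = (dev[:, :, 1] * dev[:, :, 2]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr_xy = np.where(sd[:, 0] * sd[:, 1] > 0, cov_xy / (sd[:, 0] * sd[:, 1]), 0.0)
        corr_xz = np.where(sd[:, 0] * sd[:, 2] > 0, cov_xz / (sd[:, 0] * sd[:, 2]), 0.0)
        corr_yz = np.where(sd[:, 1] * sd[:, 2] > 0, cov_yz / (sd[:, 1] * sd[:, 2]), 0.0)
    corr = np.stack([corr_xy, corr_xz, corr_yz], axis=1).clip(-1.0, 1.0)
    # spectral energy: non-DC Fourier power, scaled to mean signal power
    spec = np.fft.rfft(frames, axis=1)
    power = np.abs(spec) ** 2
    if spf % 2 == 0:  # rfft halves the band; double interior bins
        power[:, 1:-1, :] *= 2.0
    else:
        power[:, 1:, :] *= 2.0
    energy = power[:, 1:, :].sum(axis=1) / spf**2
    return np.concatenate([means, var, corr, energy], axis=1)


def compute_features(frame: np.ndarray) -> np.ndarray:
    """The 12 key-values of a single frame of shape ``(spf, 3)``."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] < 2:
        raise ValueError("frame must have shape (n >= 2, 3)")
    return _features_from_array(frame[None])[0]


def features_for_trace(
    trace: AccelTrace, frame_length_s: float = EPOCH_SECONDS
) -> pd.DataFrame:
    """Feature table for every complete frame of a trace.

    Columns: ``child_id``, ``frame_index``, ``start_time`` plus the 12
    feature columns in fixed order.
    """
    frames = segment_frames(trace, frame_length_s)
    feats = _features_from_array(frames) if len(frames) else np.empty((0, 12))
    step = pd.to_timedelta(frame_length_s, unit="s")
    df = pd.DataFrame(feats, columns=list(FEATURE_COLUMNS))
    df.insert(0, "start_time", trace.start_time + step * np.arange(len(frames)))
    df.insert(0, "frame_index", np.arange(len(frames)))
    df.insert(0, "child_id", trace.child_id)
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["start_time"])
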