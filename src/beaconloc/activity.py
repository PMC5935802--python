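"""Jerk-proportional activity metric from 100 Hz triaxial acceleration.

The per-epoch metric is computed in three steps: (1) Euclidean magnitude of
the (ax, ay, az) signal, (2) moving standard deviation of the magnitude with
a 5-sample window, (3) mean of that SD over nonoverlapping 1000-sample
blocks (10 s at 100 Hz).  Steps 1–2 cancel the gravitational component
regardless of sensor orientation (the SD is shift-invariant), and the block
mean is proportional to the jerk level over the epoch.

Window alignment and SD flavour are not dictated by the construction; this
implementation uses a *centered* window, *sample* SD (denominator n−1) and
shrunken windows at the series edges.

Epochs are then classified into low / middle / high activity by a 3-cluster
k-means on the scalar metric, fitted per recording.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

SAMPLE_RATE_HZ = 100
SD_WINDOW = 5
EPOCH_SAMPLES = 1000  # 10 s at 100 Hz

LEVELS = ("low", "middle", "high")


class DegenerateMetricError(ValueError):
    """Fewer than 3 distinct metric values: k-means levels are undefined."""


@dataclass(frozen=True)
class ActivityEpoch:
    t_index: int
    metric: float
    level: str | None = None


def accel_magnitude(ax, ay, az) -> np.ndarray:
    """Euclidean norm of the acceleration vector, in g-units.

    Accepts scalars or arrays (element-wise).
    """
    return np.sqrt(np.square(ax) + np.square(ay) + np.square(az))


def moving_sd(series: np.ndarray, window: int = SD_WINDOW) -> np.ndarray:
    """Centered moving sample SD (ddof=1) with shrunken edge windows.

    At position i the window is ``series[max(0, i-h) : i+h+1]`` with
    ``h = window // 2``; a window that shrinks to a single sample yields 0.
    """
    x = np.asarray(series, dtype=float)
    h = window // 2
    n = len(x)
    out = np.empty(n)
    if n == 0:
        return out
    # two-pass per window: numerically shift-invariant, so a constant
    # (gravity) offset cancels exactly instead of amplifying roundoff
    if n >= window:
        win = np.lib.stride_tricks.sliding_window_view(x, window)
        out[h : n - h] = win.std(axis=1, ddof=1)
    for i in list(range(min(h, n))) + list(range(max(n - h, 0), n)):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        w = x[lo:hi]
        out[i] = np.std(w, ddof=1) if len(w) >= 2 else 0.0
    return out


def jerk_metric(
    magnitudes: np.ndarray,
    window: int = SD_WINDOW,
    epoch_samples: int = EPOCH_SAMPLES,
) -> np.ndarray:
    """Per-epoch jerk-proportional metric from the magnitude series.

    Moving SD (window 5) then mean over consecutive nonoverlapping blocks of
    ``epoch_samples``; a trailing partial block is dropped.  Output length is
    ``len(magnitudes) // epoch_samples``; an input shorter than one block
    yields an empty array with a warning.
    """
    x = np.asarray(magnitudes, dtype=float)
    n_epochs = len(x) // epoch_samples
    if n_epochs == 0:
        warnings.warn(
            f"acceleration series of {len(x)} samples is shorter than one "
            f"{epoch_samples}-sample epoch; no metric computed",
            stacklevel=2,
        )
        return np.empty(0)
    sd = moving_sd(x, window=window)
    usable = sd[: n_epochs * epoch_samples]
    return usable.reshape(n_epochs, epoch_samples).mean(axis=1)


def classify_levels(
    metrics: np.ndarray,
    n_levels: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> list[str]:
    """k-means classification of per-epoch metrics into low/middle/high.

    Clusters are fitted on the scalar metric per recording and relabelled by
    ascending center, so the lowest-center cluster is "low" and the highest
    "high".  Deterministic under a fixed seed.  Raises
    :class:`DegenerateMetricError` with fewer than ``n_levels`` distinct
    values.
    """
    x = np.asarray(metrics, dtype=float)
    if len(np.unique(x)) < n_levels:
        raise DegenerateMetricError(
            f"need at least {n_levels} distinct metric values, got {len(np.unique(x))}"
        )
    km = KMeans(n_clusters=n_levels, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    rank = np.empty(n_levels, dtype=int)
    rank[order] = np.arange(n_levels)
    names = LEVELS if n_levels == 3 else tuple(f"level{i}" for i in range(n_levels))
    return [names[rank[l]] for l in labels]


def activity_epochs(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    seed: int = 0,
) -> list[ActivityEpoch]:
    """Full pipeline: magnitude → jerk metric → k-means levels, per 10-s epoch."""
    metric = jerk_metric(accel_magnitude(np.asarray(ax), np.asarray(ay), np.asarray(az)))
    levels = classify_levels(metric, seed=seed)
    return [
        ActivityEpoch(t_index=k, metric=float(m), level=lv)
        for k, (m, lv) in enumerate(zip(metric, levels))
    ]
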