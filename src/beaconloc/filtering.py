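"""Graph-constrained Bayesian localization: predict/update with exception management.

Per 10-s epoch *k* the recursion is

    X~_k = norm(X_{k-1} · M_k)          (a priori motion model)
    X_k  = norm(X~_k ⊙ Y_k)             (state update, point-wise product)

with ``X_0`` uniform over the N grouped areas, ``M_k`` from the selected
motion model (possibly step-count-modulated) and ``Y_k`` the normalized
per-area RSSI measurement vector.  The most probable area (MAP) is the
argmax of the posterior, ties broken by lowest area index.

Three exception rules make the recursion robust:

1. **degenerate posterior** — at least one reading was heard (c ≠ 0) but the
   product X~ ⊙ Y is zero everywhere (measurement support disjoint from the
   motion prior, e.g. a reflection glitch): the state is resampled to
   uniform and the reported MAP held at the previous epoch's value.
2. **no measurement** — c = 0: no update is performed; state and MAP carry
   forward unchanged.
3. **anti-hopping** — a MAP excursion from area A to area B is reported only
   once B has persisted for at least 2 consecutive samples (20 s), and then
   retroactively from the first sample of the stable run; single-sample
   hops A→B→A are suppressed.  The posterior itself is left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .floorplan import AreaGraph, Beacon, build_adjacency
from .measurement import MeasurementVector, RssiSample, build_measurement
from .motion import MotionModel, StepEpoch, transition_matrix

logger = logging.getLogger(__name__)

NORM_TOL = 1e-12

EXC_DEGENERATE = "degenerate_posterior"
EXC_NO_MEASUREMENT = "no_measurement"
EXC_HOP = "hop_candidate"


class DegenerateStateError(ArithmeticError):
    """norm() of an all-zero vector; must be routed through exception management."""


@dataclass(frozen=True)
class StateVector:
    """Posterior area probabilities at one epoch; always sums to 1."""

    t_index: int
    probs: np.ndarray

    def map_index(self) -> int:
        # np.argmax returns the first (lowest) index on ties
        return int(np.argmax(self.probs))


def norm(vector: np.ndarray) -> np.ndarray:
    """Divide by the vector sum; raises on an all-zero vector."""
    v = np.asarray(vector, dtype=float)
    s = v.sum()
    if s <= 0.0:
        raise DegenerateStateError("cannot normalize an all-zero vector")
    return v / s


def uniform_state(n: int, t_index: int = 0) -> StateVector:
    return StateVector(t_index=t_index, probs=np.full(n, 1.0 / n))


def predict(state: StateVector, transition: np.ndarray) -> StateVector:
    """A priori estimate X~ = norm(X · M)."""
    m = np.asarray(transition, dtype=float)
    if (m < 0).any():
        raise ValueError("transition matrix must be nonnegative")
    return StateVector(t_index=state.t_index + 1, probs=norm(state.probs @ m))


def update(prior: StateVector, meas: MeasurementVector) -> StateVector:
    """Posterior X = norm(X~ ⊙ Y); requires a detection (c > 0).

    Raises :class:`DegenerateStateError` when the point-wise product is zero
    everywhere — the exception-1 path.
    """
    if not meas.has_detection:
        raise ValueError("update requires a measurement with c > 0")
    return StateVector(t_index=prior.t_index, probs=norm(prior.probs * meas.Y))


def apply_exceptions(
    prev_state: StateVector,
    prev_map: int,
    event: str,
    t_index: int,
) -> tuple[StateVector, int]:
    """Resolve exception rules 1 and 2 into the epoch's (state, MAP).

    ``degenerate_posterior`` → uniform resample, MAP held at the previous
    epoch's value; ``no_measurement`` → state and MAP carried forward.
    (Rule 3, anti-hopping, acts on the whole MAP sequence: see
    :func:`smooth_map_sequence`.)
    """
    n = len(prev_state.probs)
    if event == EXC_DEGENERATE:
        return uniform_state(n, t_index), prev_map
    if event == EXC_NO_MEASUREMENT:
        return StateVector(t_index=t_index, probs=prev_state.probs.copy()), prev_map
    raise ValueError(f"unknown exception event {event!r}")


def smooth_map_sequence(raw_map: Sequence[int], min_run: int = 2) -> list[int]:
    """Anti-hopping smoothing of the raw MAP sequence.

    A new area is committed only once it has persisted for ``min_run``
    consecutive samples, and is then reported from the first sample of that
    stable run; shorter excursions are replaced by the area committed before
    them.  The first observed area is committed unconditionally.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    raw = list(raw_map)
    if not raw:
        return []
    # run-length encode
    runs: list[tuple[int, int]] = []  # (area, length)
    for a in raw:
        if runs and runs[-1][0] == a:
            runs[-1] = (a, runs[-1][1] + 1)
        else:
            runs.append((a, 1))
    out: list[int] = []
    current = runs[0][0]
    for area, length in runs:
        if area != current and length >= min_run:
            current = area
        out.extend([current] * length)
    return out


@dataclass
class LocalizationTrace:
    """Per-epoch output of one receiver's filter run."""

    receiver_id: str
    area_ids: list[str]
    t_index: np.ndarray
    posteriors: np.ndarray  # (T, N)
    map_raw: np.ndarray  # (T,) int area indices
    map_smoothed: np.ndarray  # (T,)
    exceptions: list[tuple[str, ...]]  # flags fired per epoch

    @property
    def n_epochs(self) -> int:
        return len(self.t_index)

    def smoothed_area_ids(self) -> list[str]:
        return [self.area_ids[i] for i in self.map_smoothed]

    def to_dataframe(self, include_probs: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_index": self.t_index,
                "receiver_id": self.receiver_id,
                "map_area_raw": [self.area_ids[i] for i in self.map_raw],
                "map_area_smoothed": self.smoothed_area_ids(),
                "exception_flags": [";".join(f) for f in self.exceptions],
            }
        )
        if include_probs:
            for j, aid in enumerate(self.area_ids):
                df[f"prob_{aid}"] = self.posteriors[:, j]
        return df


def _group_samples(
    rssi_stream: Iterable[RssiSample],
) -> dict[int, list[RssiSample]]:
    by_epoch: dict[int, list[RssiSample]] = {}
    for s in rssi_stream:
        by_epoch.setdefault(s.t_index, []).append(s)
    return by_epoch


def _steps_lookup(step_stream) -> Mapping[int, int]:
    if step_stream is None:
        return {}
    if isinstance(step_stream, Mapping):
        return {int(k): int(v) for k, v in step_stream.items()}
    out: dict[int, int] = {}
    for e in step_stream:
        if isinstance(e, StepEpoch):
            out[e.t_index] = e.steps
        else:
            k, v = e
            out[int(k)] = int(v)
    return out


def run_filter(
    graph: AreaGraph,
    beacons: Sequence[Beacon],
    model: MotionModel,
    rssi_stream: Iterable[RssiSample],
    step_stream=None,
    *,
    n_epochs: int | None = None,
    min_run: int = 2,
    receiver_id: str = "R1",
) -> LocalizationTrace:
    """Run the full predict/update recursion over an epoch-aligned RSSI stream.

    ``rssi_stream`` holds one receiver's samples (t_index-binned);
    ``step_stream`` maps epoch → step count (a mapping, an iterable of
    :class:`~beaconloc.motion.StepEpoch`, or ``(t_index, steps)`` pairs).
    Epochs missing a step record count as 0 steps (likely stationary) with a
    logged warning.  The trace covers epochs ``0 … n_epochs-1`` (default:
    up to the last epoch present in the RSSI stream); epochs with no samples
    fire the no-measurement rule.  Deterministic: identical inputs yield an
    identical trace.
    """
    by_epoch = _group_samples(rssi_stream)
    steps = _steps_lookup(step_stream)
    if n_epochs is None:
        n_epochs = (max(by_epoch) + 1) if by_epoch else 0
    n = graph.n_areas
    adjacency = build_adjacency(graph)

    posteriors = np.empty((n_epochs, n))
    map_raw = np.empty(n_epochs, dtype=int)
    flags: list[tuple[str, ...]] = []

    state = uniform_state(n, t_index=-1)
    prev_map = state.map_index()
    missing_step_epochs = 0

    for k in range(n_epochs):
        epoch_flags: list[str] = []
        meas = build_measurement(by_epoch.get(k, []), beacons, graph, t_index=k)
        if not meas.has_detection:
            state, prev_map = apply_exceptions(state, prev_map, EXC_NO_MEASUREMENT, k)
            epoch_flags.append(EXC_NO_MEASUREMENT)
            logger.debug("epoch %d receiver %s: rule no_measurement fired", k, receiver_id)
        else:
            if model.uses_steps and k not in steps:
                missing_step_epochs += 1
            step_k = steps.get(k, 0)
            m = transition_matrix(model, adjacency, graph.areas, step_k)
            prior = predict(state, m)
            try:
                state = update(prior, meas)
                prev_map = state.map_index()
            except DegenerateStateError:
                state, prev_map = apply_exceptions(state, prev_map, EXC_DEGENERATE, k)
                epoch_flags.append(EXC_DEGENERATE)
                logger.info(
                    "epoch %d receiver %s: rule degenerate_posterior fired", k, receiver_id
                )
        posteriors[k] = state.probs
        map_raw[k] = prev_map
        flags.append(tuple(epoch_flags))

    if missing_step_epochs:
        logger.warning(
            "receiver %s: %d epoch(s) had no step record; treated as 0 steps",
            receiver_id,
            missing_step_epochs,
        )

    smoothed = np.asarray(smooth_map_sequence(list(map_raw), min_run=min_run), dtype=int)
    if n_epochs == 0:
        smoothed = np.empty(0, dtype=int)
    for k in range(n_epochs):
        if smoothed[k] != map_raw[k] and EXC_HOP not in flags[k]:
            flags[k] = flags[k] + (EXC_HOP,)

    return LocalizationTrace(
        receiver_id=receiver_id,
        area_ids=graph.area_ids,
        t_index=np.arange(n_epochs),
        posteriors=posteriors,
        map_raw=map_raw,
        map_smoothed=smoothed,
        exceptions=flags,
    )
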