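"""RSSI → per-area measurement probabilities for one epoch.

Each beacon reading is mapped to a heuristic proximity probability
``y ∈ [0, 1]``: 1 when the receiver is within ~1 m of the beacon
(RSSI ≥ −45 dBm), 0 when the link is dead (RSSI < −90 dBm), and linearly
interpolated in between — received power falls with distance, so the clipped
linear ramp is the simplest monotone map honouring both anchors.  An area
served by several beacons takes the *maximum* of its beacons' probabilities
(nearest-beacon logic); summing would overweight large areas.

The per-area vector ``y`` is normalized to ``Y = y / c`` with ``c = Σy``;
``c = 0`` flags an epoch with no usable detection, handled downstream by
exception management.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .floorplan import AreaGraph, Beacon

RSSI_NEAR_DBM = -45.0   # receiver within ~1 m of the beacon
RSSI_CUTOFF_DBM = -90.0  # communication interrupted below this


class UnknownBeaconError(KeyError):
    pass


@dataclass(frozen=True)
class RssiSample:
    """One (receiver, beacon) RSSI reading, already binned to an epoch."""

    t_index: int
    receiver_id: str
    beacon_id: str
    rssi: float


@dataclass(frozen=True)
class MeasurementVector:
    """Per-area detection probabilities for one epoch.

    ``y`` holds the unnormalized per-area entries, ``c = Σy`` and
    ``Y = y / c`` when ``c > 0``; ``Y`` is ``None`` when nothing was heard.
    """

    t_index: int
    y: np.ndarray
    c: float
    Y: np.ndarray | None

    @property
    def has_detection(self) -> bool:
        return self.c > 0.0


def rssi_to_probability(
    rssi: float,
    near_dbm: float = RSSI_NEAR_DBM,
    cutoff_dbm: float = RSSI_CUTOFF_DBM,
) -> float:
    """Clipped linear proximity probability: 0 below −90 dBm, 1 above −45 dBm.

    Monotone nondecreasing in RSSI; the default anchors give
    ``y = (rssi + 90) / 45`` on the ramp.
    """
    if not np.isfinite(rssi):
        raise ValueError(f"non-finite RSSI {rssi!r}")
    if rssi < cutoff_dbm:
        return 0.0
    if rssi >= near_dbm:
        return 1.0
    return (rssi - cutoff_dbm) / (near_dbm - cutoff_dbm)


RssiMap = Callable[[float], float]


def build_measurement(
    epoch_samples: Iterable[RssiSample],
    beacons: Sequence[Beacon],
    graph: AreaGraph,
    t_index: int | None = None,
    rssi_map: RssiMap = rssi_to_probability,
) -> MeasurementVector:
    """Aggregate one epoch's RSSI samples into a per-area MeasurementVector.

    Per area: the maximum mapped probability over that area's beacons heard
    this epoch (0 if none).  Raises :class:`UnknownBeaconError` naming any
    beacon_id absent from the map.
    """
    beacon_area = {b.beacon_id: b.area_id for b in beacons}
    n = graph.n_areas
    y = np.zeros(n)
    seen_epoch = t_index
    for s in epoch_samples:
        if s.beacon_id not in beacon_area:
            raise UnknownBeaconError(f"unknown beacon_id {s.beacon_id!r}")
        if seen_epoch is None:
            seen_epoch = s.t_index
        i = graph.index_of(beacon_area[s.beacon_id])
        y[i] = max(y[i], rssi_map(s.rssi))
    c = float(y.sum())
    Y = y / c if c > 0 else None
    return MeasurementVector(t_index=seen_epoch if seen_epoch is not None else -1,
                             y=y, c=c, Y=Y)


def majority_vote(map_indices: Sequence[int | None]) -> int | None:
    """Optional post-hoc fusion of several receivers' MAP areas for one epoch.

    Returns the most common non-missing index (ties → lowest index), or
    ``None`` when every receiver is missing.
    """
    votes = [i for i in map_indices if i is not None]
    if not votes:
        return None
    counts = np.bincount(votes)
    return int(np.argmax(counts))
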