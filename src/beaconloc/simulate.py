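"""Synthetic walking trials: ground truth, RSSI, step counts, raw acceleration.

The generator emulates the data a wrist-worn ActiGraph-style receiver
produces while a technician walks a prescribed route through the building:

* a ground-truth area trace at 10-s epoch resolution, from a walk plan of
  (area, dwell) stops with travel times derived from edge distances and the
  walking speed;
* per-beacon RSSI readings per epoch from a log-distance path-loss model
  (reference −45 dBm at 1 m, exponent 2.5, Gaussian shadowing σ = 4 dB),
  with readings below −90 dBm dropped, occasional strong glitches on a
  non-adjacent beacon (reflection/scattering), full-epoch dropouts, and
  beacons on another floor suppressed entirely;
* device-style step counts (cadence-scaled while walking, 0–2 while
  dwelling) and 100 Hz triaxial acceleration (1 g baseline plus a walking
  oscillation whose amplitude scales with speed).

Trial presets mirror the standard protocol: trial 1 normal pace (1.4 m/s,
≥3 min per area), trial 2 slow (0.9 m/s, ≥2 min), trial 3 fast (2.0 m/s,
≥1 min), trial 4 unprescribed (randomized route, dwells and speed).
All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .evaluation import GroundTruthTrace
from .floorplan import AreaGraph, Beacon
from .measurement import RSSI_CUTOFF_DBM
from .motion import StepEpoch

DWELL_AREA_KINDS = ("room", "social")


@dataclass(frozen=True)
class RssiModel:
    """Log-distance path-loss channel with shadowing, glitches and dropout."""

    ref_power_dbm: float = -45.0  # received power at 1 m
    path_loss_exponent: float = 2.5
    noise_sd_db: float = 4.0
    glitch_prob: float = 0.02
    glitch_magnitude_db: float = 15.0
    dropout_prob: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.glitch_prob, self.dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def clean(self) -> "RssiModel":
        """Noise-free copy: σ = 0, no glitches, no dropout."""
        return replace(self, noise_sd_db=0.0, glitch_prob=0.0, dropout_prob=0.0)


@dataclass
class SimulationConfig:
    """Everything one synthetic trial needs besides the map itself."""

    walk_plan: list[tuple[str, float]]  # (area_id, dwell seconds)
    speed_mps: float = 1.4
    epoch_s: float = 10.0
    rssi: RssiModel = field(default_factory=RssiModel)
    seed: int = 0
    accel_rate_hz: int = 100

    def __post_init__(self) -> None:
        if self.speed_mps <= 0:
            raise ValueError("speed must be positive")
        for area, dwell in self.walk_plan:
            if dwell <= 0:
                raise ValueError(f"dwell at {area!r} must be positive")


@dataclass
class SyntheticTrial:
    truth: GroundTruthTrace
    rssi_samples: list  # list[RssiSample]
    steps: list[StepEpoch]
    accel: dict  # {"t": s, "ax": g, "ay": g, "az": g} at accel_rate_hz
    config: SimulationConfig


# Prescribed routes stop in rooms and social areas; trials start and finish
# in the same location.  Route areas refer to the packaged example map.
DEFAULT_ROUTE = ["1R1", "1R2", "1S1", "1R3", "2R1", "2S1", "2R2", "1R1"]

TRIAL_PRESETS = {
    1: {"speed_mps": 1.4, "dwell_s": 180.0},  # normal pace, >= 3 min per area
    2: {"speed_mps": 0.9, "dwell_s": 120.0},  # slow pace, >= 2 min
    3: {"speed_mps": 2.0, "dwell_s": 60.0},  # fast pace, >= 1 min
}


def trial_config(
    trial: int,
    graph: AreaGraph | None = None,
    seed: int = 0,
    route: Sequence[str] | None = None,
    rssi: RssiModel | None = None,
) -> SimulationConfig:
    """Build the SimulationConfig for one of the four trial presets.

    Trials 1–3 use the prescribed route and their preset speed/dwell;
    trial 4 draws route, dwells (30–240 s) and speed (0.8–2.0 m/s) at
    random from the map's rooms and social areas.
    """
    if trial in TRIAL_PRESETS:
        preset = TRIAL_PRESETS[trial]
        plan_route = list(route) if route is not None else list(DEFAULT_ROUTE)
        plan = [(a, preset["dwell_s"]) for a in plan_route]
        return SimulationConfig(
            walk_plan=plan,
            speed_mps=preset["speed_mps"],
            seed=seed,
            rssi=rssi or RssiModel(),
        )
    if trial != 4:
        raise ValueError(f"unknown trial {trial}; expected 1-4")
    if graph is None:
        raise ValueError("trial 4 (random) needs the area graph to draw a route")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    stops = [a.area_id for a in graph.areas if a.kind in DWELL_AREA_KINDS]
    n_stops = int(rng.integers(5, 9))
    order = list(rng.choice(stops, size=n_stops, replace=True))
    # start and finish in the same location, avoid immediate repeats
    route4 = [stops[0]]
    for a in order:
        if a != route4[-1]:
            route4.append(a)
    route4.append(route4[0])
    plan = [(a, float(rng.uniform(30.0, 240.0))) for a in route4]
    return SimulationConfig(
        walk_plan=plan,
        speed_mps=float(rng.uniform(0.8, 2.0)),
        seed=seed,
        rssi=rssi or RssiModel(),
    )


def _timeline(
    graph: AreaGraph, config: SimulationConfig
) -> list[tuple[str, float, bool]]:
    """(area, duration s, moving) segments of the walk, in order.

    Travel between consecutive stops follows the distance-shortest path;
    each edge's travel time is split half-and-half between its endpoint
    areas, so intermediate corridors are occupied for their share of the
    walk.
    """
    g = graph.to_networkx()
    segments: list[tuple[str, float, bool]] = []
    plan = config.walk_plan
    v = config.speed_mps
    for i, (area, dwell) in enumerate(plan):
        graph.index_of(area)  # validate
        segments.append((area, float(dwell), False))
        if i + 1 >= len(plan):
            break
        target = plan[i + 1][0]
        if target == area:
            continue
        try:
            path = nx.shortest_path(g, area, target, weight="distance")
        except nx.NetworkXNoPath:
            raise ValueError(f"no walking path between {area!r} and {target!r}")
        for u, w in zip(path[:-1], path[1:]):
            t_edge = graph.distance(u, w) / v
            segments.append((u, t_edge / 2.0, True))
            segments.append((w, t_edge / 2.0, True))
    return segments


def plan_walk(graph: AreaGraph, config: SimulationConfig) -> GroundTruthTrace:
    """Epoch-resolution ground-truth trace for the configured walk.

    The occupied area of epoch k is the area at the epoch's midpoint; a
    trailing partial epoch is dropped.
    """
    segments = _timeline(graph, config)
    total = sum(d for _, d, _ in segments)
    n_epochs = int(total // config.epoch_s)
    bounds = np.cumsum([d for _, d, _ in segments])
    areas: list[str] = []
    moving = np.zeros(n_epochs, dtype=bool)
    for k in range(n_epochs):
        mid = (k + 0.5) * config.epoch_s
        j = int(np.searchsorted(bounds, mid, side="right"))
        j = min(j, len(segments) - 1)
        areas.append(segments[j][0])
        moving[k] = segments[j][2]
    return GroundTruthTrace(area_ids=areas, epoch_s=config.epoch_s, moving=moving)


def _area_floor(graph: AreaGraph, area_id: str):
    return graph.area(area_id).floor


def _beacon_distances(graph: AreaGraph, beacons: Sequence[Beacon]) -> dict:
    """Walking distance (m) from every area to every beacon's area; 1 m within
    the same area."""
    g = graph.to_networkx()
    sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
    out: dict[tuple[str, str], float] = {}
    for a in graph.area_ids:
        for b in beacons:
            out[(a, b.beacon_id)] = 1.0 if b.area_id == a else float(sp[a][b.area_id])
    return out


def synthesize_rssi(
    truth: GroundTruthTrace,
    graph: AreaGraph,
    beacons: Sequence[Beacon],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    receiver_id: str = "R1",
) -> list:
    """Per-epoch RSSI readings from the log-distance channel.

    For each epoch and each beacon sharing the walker's floor:
    ``rssi = P_1m − 10·n·log10(max(d, 1)) + N(0, σ²)``; readings below the
    −90 dBm cutoff are dropped.  With the configured probabilities, one
    spurious strong reading is injected on a non-adjacent beacon (glitch)
    or the epoch's readings are removed entirely (dropout).
    """
    from .measurement import RssiSample

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ch = config.rssi
    dist = _beacon_distances(graph, beacons)
    samples: list[RssiSample] = []
    adjacent = {a: {a} for a in graph.area_ids}
    for e in graph.edges:
        u, v = sorted(e)
        adjacent[u].add(v)
        adjacent[v].add(u)

    for k, area in enumerate(truth.area_ids):
        floor = _area_floor(graph, area)
        epoch_readings: list[RssiSample] = []
        for b in beacons:
            b_floor = _area_floor(graph, b.area_id)
            if floor != "both" and b_floor != "both" and b_floor != floor:
                continue  # cross-floor propagation suppressed
            d = dist[(area, b.beacon_id)]
            rssi = ch.ref_power_dbm - 10.0 * ch.path_loss_exponent * np.log10(max(d, 1.0))
            if ch.noise_sd_db > 0:
                rssi += rng.normal(0.0, ch.noise_sd_db)
            if rssi >= RSSI_CUTOFF_DBM:
                epoch_readings.append(
                    RssiSample(t_index=k, receiver_id=receiver_id,
                               beacon_id=b.beacon_id, rssi=float(rssi))
                )
        if ch.glitch_prob > 0 and rng.random() < ch.glitch_prob:
            far = [
                b for b in beacons
                if b.area_id not in adjacent[area]
            ]
            if far:
                b = far[int(rng.integers(len(far)))]
                d = dist[(area, b.beacon_id)]
                rssi = (
                    ch.ref_power_dbm
                    - 10.0 * ch.path_loss_exponent * np.log10(max(d, 1.0))
                    + ch.glitch_magnitude_db
                )
                if rssi >= RSSI_CUTOFF_DBM:
                    epoch_readings = [
                        s for s in epoch_readings if s.beacon_id != b.beacon_id
                    ]
                    epoch_readings.append(
                        RssiSample(t_index=k, receiver_id=receiver_id,
                                   beacon_id=b.beacon_id, rssi=float(rssi))
                    )
        if ch.dropout_prob > 0 and rng.random() < ch.dropout_prob:
            epoch_readings = []
        samples.extend(epoch_readings)
    return samples


def cadence_hz(speed_mps: float) -> float:
    """Step frequency model: ≈2 steps/s at normal pace, scaling with √speed."""
    return 2.0 * np.sqrt(speed_mps / 1.4)


STAIR_JERK_FACTOR = 2.0  # stair climbing is jerkier than level walking


def synthesize_motion(
    truth: GroundTruthTrace,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    kinds: Sequence[str] | None = None,
) -> tuple[list[StepEpoch], dict]:
    """Device-style step counts and 100 Hz triaxial acceleration.

    Moving epochs count ≈ cadence·10 steps (always > 2 by construction);
    dwelling epochs count 0–2.  Acceleration rides a 1 g gravity baseline;
    moving epochs add a cadence-frequency oscillation whose amplitude scales
    with speed — doubled on stairs, where gait is jerkiest — so the jerk
    metric separates dwelling, level walking and stair climbing.
    ``kinds`` optionally gives the occupied area's kind per epoch (used for
    the stair factor; all-level walking assumed when absent).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_epochs = truth.n_epochs
    moving = (
        truth.moving
        if truth.moving is not None
        else np.zeros(n_epochs, dtype=bool)
    )
    cad = cadence_hz(config.speed_mps)
    steps: list[StepEpoch] = []
    for k in range(n_epochs):
        if moving[k]:
            n = int(round(cad * config.epoch_s + rng.normal(0.0, 1.5)))
            n = max(n, 3)  # a walking epoch always exceeds the 2-step threshold
        else:
            n = int(rng.integers(0, 3))
        steps.append(StepEpoch(t_index=k, steps=n))

    rate = config.accel_rate_hz
    per_epoch = int(rate * config.epoch_s)
    total = n_epochs * per_epoch
    t = np.arange(total) / rate
    ax = rng.normal(0.0, 0.002, total)
    ay = rng.normal(0.0, 0.002, total)
    az = 1.0 + rng.normal(0.0, 0.003, total)
    amp = 0.08 * config.speed_mps
    for k in range(n_epochs):
        if moving[k]:
            sl = slice(k * per_epoch, (k + 1) * per_epoch)
            factor = (
                STAIR_JERK_FACTOR if kinds is not None and kinds[k] == "stairs" else 1.0
            )
            phase = rng.uniform(0.0, 2.0 * np.pi)
            az[sl] += factor * amp * np.sin(2.0 * np.pi * cad * t[sl] + phase)
            az[sl] += rng.normal(0.0, 0.005 * factor * config.speed_mps, per_epoch)
    return steps, {"t": t, "ax": ax, "ay": ay, "az": az}


def simulate_trial(
    graph: AreaGraph,
    beacons: Sequence[Beacon],
    config: SimulationConfig,
) -> SyntheticTrial:
    """Generate one complete synthetic trial; bit-identical under one seed."""
    truth = plan_walk(graph, config)
    ss = np.random.SeedSequence([config.seed, 7])
    rssi_rng, motion_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    rssi = synthesize_rssi(truth, graph, beacons, config, rng=rssi_rng)
    kinds = [graph.area(a).kind for a in truth.area_ids]
    steps, accel = synthesize_motion(truth, config, rng=motion_rng, kinds=kinds)
    return SyntheticTrial(
        truth=truth, rssi_samples=rssi, steps=steps, accel=accel, config=config
    )
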