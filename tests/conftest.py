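import numpy as np
import pytest

from beaconloc import (
    Area,
    AreaGraph,
    Beacon,
    MotionModel,
    RssiModel,
    load_example_map,
    simulate_trial,
    trial_config,
)


def make_graph(kinds, edges, distances=None):
    """Small helper: areas A0..A(n-1) with given kinds and index-pair edges."""
    areas = [Area(area_id=f"A{i}", kind=k, floor=1) for i, k in enumerate(kinds)]
    edge_set = {frozenset((f"A{i}", f"A{j}")) for i, j in edges}
    dist = {}
    if distances:
        for (i, j), d in distances.items():
            dist[frozenset((f"A{i}", f"A{j}"))] = d
    return AreaGraph(areas=areas, edges=edge_set, edge_distances=dist)


def beacons_for(graph):
    """One beacon per area, named like the area."""
    return [
        Beacon(beacon_id=a.area_id, area_id=a.area_id, floor=1) for a in graph.areas
    ]


def random_connected_graph(rng, n, kinds=("room", "social", "corridor")):
    """Random connected graph on n areas: a random spanning tree plus extras."""
    edges = set()
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(i)]
        edges.add((min(order[i], j), max(order[i], j)))
    for _ in range(rng.integers(0, n)):
        i, j = rng.integers(n, size=2)
        if i != j:
            edges.add((min(i, j), max(i, j)))
    kind_list = [kinds[rng.integers(len(kinds))] for _ in range(n)]
    return make_graph(kind_list, edges)


@pytest.fixture(scope="session")
def example_map():
    return load_example_map()


@pytest.fixture(scope="session")
def trial1_clean(example_map):
    beacons, _, graph = example_map
    cfg = trial_config(1, seed=11, rssi=RssiModel().clean())
    return simulate_trial(graph, beacons, cfg)


@pytest.fixture(scope="session")
def trial1_noisy(example_map):
    beacons, _, graph = example_map
    cfg = trial_config(1, seed=11)
    return simulate_trial(graph, beacons, cfg)


@pytest.fixture
def two_area_graph():
    return make_graph(["room", "room"], [(0, 1)])
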