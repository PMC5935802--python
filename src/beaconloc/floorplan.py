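"""Building representation: areas, beacon placements, and the walking-pathway graph.

A building is modelled as a graph whose nodes are *grouped areas* (a room, a
social area, a corridor section, or the stairway) and whose edges are walking
pathways between them.  Several physical beacons may serve one area (long
corridors and large social areas carry two); localization states are the
grouped areas, never the raw beacons.

The sparse adjacency matrix ``A`` of this graph is the backbone of every
motion model: ``a_ij = 1`` iff areas *i* and *j* are connected by a walking
pathway, and ``a_ii = 1`` so that staying put is always representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

AREA_KINDS = ("room", "social", "corridor", "stairs")

# Typical walking distance between neighbouring beacon reference points in an
# office building; also ensures an area takes about one 10-s epoch to traverse
# at a brisk pace, matching the beacon density the placement rules produce.
DEFAULT_EDGE_DISTANCE_M = 25.0


class MapValidationError(ValueError):
    """A beacon-map configuration violates the schema or graph invariants."""


@dataclass(frozen=True)
class Beacon:
    """A fixed BLE transmitter serving exactly one grouped area."""

    beacon_id: str
    area_id: str
    floor: int
    placement_note: str = ""


@dataclass(frozen=True)
class Area:
    """A grouped map node: room, social area, corridor section, or stairway.

    ``floor`` is an integer, or the string ``"both"`` for a stairway that
    connects two floors through a single beacon.
    """

    area_id: str
    kind: str
    floor: int | str

    def __post_init__(self) -> None:
        if self.kind not in AREA_KINDS:
            raise MapValidationError(
                f"area {self.area_id!r}: unknown kind {self.kind!r}; "
                f"expected one of {AREA_KINDS}"
            )

    def on_floor(self, floor: int) -> bool:
        return self.floor == "both" or self.floor == floor


@dataclass
class AreaGraph:
    """Ordered grouped areas plus walking-pathway edges.

    The order of ``areas`` fixes the state indices 1…N for the whole run;
    every matrix and state vector downstream uses this indexing.
    """

    areas: list[Area]
    edges: set[frozenset[str]]
    edge_distances: dict[frozenset[str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {a.area_id: i for i, a in enumerate(self.areas)}
        if len(self._index) != len(self.areas):
            seen: set[str] = set()
            for a in self.areas:
                if a.area_id in seen:
                    raise MapValidationError(f"duplicate area_id {a.area_id!r}")
                seen.add(a.area_id)
        for e in self.edges:
            for aid in e:
                if aid not in self._index:
                    raise MapValidationError(
                        f"edge {sorted(e)} references unknown area {aid!r}"
                    )

    def validate_connected(self) -> None:
        """Raise unless every area is reachable by walking pathways."""
        if self.areas and not nx.is_connected(self.to_networkx()):
            comps = list(nx.connected_components(self.to_networkx()))
            raise MapValidationError(
                f"area graph is disconnected: components {sorted(map(sorted, comps))}"
            )

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def area_ids(self) -> list[str]:
        return [a.area_id for a in self.areas]

    def index_of(self, area_id: str) -> int:
        try:
            return self._index[area_id]
        except KeyError:
            raise MapValidationError(f"unknown area {area_id!r}") from None

    def area(self, area_id: str) -> Area:
        return self.areas[self.index_of(area_id)]

    def distance(self, a: str, b: str) -> float:
        """Length in metres of the edge (a, b)."""
        key = frozenset((a, b))
        if key not in self.edges:
            raise MapValidationError(f"no edge between {a!r} and {b!r}")
        return self.edge_distances.get(key, DEFAULT_EDGE_DISTANCE_M)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        for e in self.edges:
            u, v = sorted(e)
            g.add_edge(u, v, distance=self.edge_distances.get(e, DEFAULT_EDGE_DISTANCE_M))
        return g


def build_adjacency(graph: AreaGraph) -> np.ndarray:
    """The N×N 0/1 walking-pathway matrix ``A`` with unit diagonal.

    ``a_ij = 1`` iff areas i and j share a walking pathway or ``i == j``;
    symmetric by construction.
    """
    n = graph.n_areas
    a = np.eye(n, dtype=float)
    for e in graph.edges:
        u, v = sorted(e)
        i, j = graph.index_of(u), graph.index_of(v)
        a[i, j] = a[j, i] = 1.0
    return a


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise MapValidationError(f"{context}: missing required key {key!r}")
    return mapping[key]


def load_beacon_map(
    config_source: str | Path | Mapping,
) -> tuple[list[Beacon], list[Area], AreaGraph]:
    """Load and validate a beacon-map configuration.

    ``config_source`` is a YAML/JSON path, a YAML string, or an
    already-parsed mapping with top-level keys ``areas``, ``beacons`` and
    ``edges``::

        areas:
          - {id: 1R1, kind: room, floor: 1}
          - {id: Stairs, kind: stairs, floor: both}
        beacons:
          - {id: 1R1, area: 1R1}
          - {id: 1C1a, area: 1C1}
        edges:
          - {between: [1R1, 1C1], distance: 8}

    Beacons sharing an ``area`` are grouped into one localization state.
    Raises :class:`MapValidationError` naming the offending entry on unknown
    references, duplicate ids, or a disconnected graph.
    """
    if isinstance(config_source, Mapping):
        raw = config_source
    else:
        text = None
        if isinstance(config_source, Path) or (
            isinstance(config_source, str)
            and "\n" not in config_source
            and Path(config_source).exists()
        ):
            text = Path(config_source).read_text()
        else:
            text = str(config_source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise MapValidationError("beacon-map config must be a mapping")

    areas: list[Area] = []
    for entry in _require(raw, "areas", "config"):
        areas.append(
            Area(
                area_id=str(_require(entry, "id", "area entry")),
                kind=str(_require(entry, "kind", f"area {entry.get('id')!r}")),
                floor=entry.get("floor", 1),
            )
        )
    area_ids = {a.area_id for a in areas}

    beacons: list[Beacon] = []
    seen_beacons: set[str] = set()
    for entry in _require(raw, "beacons", "config"):
        bid = str(_require(entry, "id", "beacon entry"))
        aid = str(_require(entry, "area", f"beacon {bid!r}"))
        if bid in seen_beacons:
            raise MapValidationError(f"duplicate beacon_id {bid!r}")
        seen_beacons.add(bid)
        if aid not in area_ids:
            raise MapValidationError(f"beacon {bid!r} references unknown area {aid!r}")
        floor = entry.get("floor")
        if floor is None:
            af = next(a.floor for a in areas if a.area_id == aid)
            floor = 0 if af == "both" else int(af)
        beacons.append(
            Beacon(
                beacon_id=bid,
                area_id=aid,
                floor=int(floor),
                placement_note=str(entry.get("note", "")),
            )
        )

    edges: set[frozenset[str]] = set()
    distances: dict[frozenset[str], float] = {}
    for entry in _require(raw, "edges", "config"):
        if isinstance(entry, Mapping):
            pair = _require(entry, "between", "edge entry")
            dist = float(entry.get("distance", DEFAULT_EDGE_DISTANCE_M))
        else:
            pair, dist = entry, DEFAULT_EDGE_DISTANCE_M
        u, v = (str(x) for x in pair)
        for aid in (u, v):
            if aid not in area_ids:
                raise MapValidationError(f"edge [{u}, {v}] references unknown area {aid!r}")
        if u == v:
            raise MapValidationError(f"self-loop edge on {u!r} not allowed")
        key = frozenset((u, v))
        edges.add(key)
        distances[key] = dist

    graph = AreaGraph(areas=areas, edges=edges, edge_distances=distances)
    graph.validate_connected()
    return beacons, areas, graph


def example_map_path() -> Path:
    """Path to the packaged two-floor, 17-beacon, 14-area example map."""
    return Path(__file__).parent / "data" / "example_map.yaml"


def load_example_map() -> tuple[list[Beacon], list[Area], AreaGraph]:
    """Load the packaged example building (two floors, 17 beacons, 14 areas)."""
    return load_beacon_map(example_map_path())
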