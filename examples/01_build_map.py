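"""Load the packaged example building and inspect its graph structure.

The building is a graph of grouped areas (rooms, social areas, corridor
sections, one stairway) connected by walking pathways; several beacons can
serve one area.  The adjacency matrix A (unit diagonal) is the backbone of
every motion model.
"""

import numpy as np

from beaconloc import build_adjacency, load_example_map

beacons, areas, graph = load_example_map()

print(f"{len(beacons)} beacons grouped into {graph.n_areas} areas:")
for area in areas:
    served = [b.beacon_id for b in beacons if b.area_id == area.area_id]
    print(f"  {area.area_id:<7} {area.kind:<9} floor {area.floor!s:<5} "
          f"beacons: {', '.join(served)}")

A = build_adjacency(graph)
print(f"\nadjacency A: {A.shape[0]}x{A.shape[1]}, "
      f"{int(A.sum() - len(A))} directed pathway entries, "
      f"symmetric={bool((A == A.T).all())}, unit diagonal={bool((np.diag(A) == 1).all())}")
row = A[graph.index_of("1C1")].astype(int)
print("A row for the main first-floor corridor (1C1):",
      {a: int(v) for a, v in zip(graph.area_ids, row)})
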