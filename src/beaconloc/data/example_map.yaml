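# Example two-floor office building: 14 grouped areas served by 17 BLE beacons.
#
# Naming: first digit = floor; letter = kind (R room, S social, C corridor);
# next digit = counter; a trailing lowercase letter marks multiple beacons
# grouped into the same long corridor / large social area. "Stairs" is one
# beacon covering the stairway on both floors.
#
# Edge distances are walking distances in metres between area reference
# points; they drive the path-loss simulator and travel times, not geometry.

areas:
  - {id: 1R1, kind: room, floor: 1}
  - {id: 1R2, kind: room, floor: 1}
  - {id: 1R3, kind: room, floor: 1}
  - {id: 1S1, kind: social, floor: 1}
  - {id: 1C1, kind: corridor, floor: 1}
  - {id: 1C2, kind: corridor, floor: 1}
  - {id: 1C3, kind: corridor, floor: 1}
  - {id: 2R1, kind: room, floor: 2}
  - {id: 2R2, kind: room, floor: 2}
  - {id: 2S1, kind: social, floor: 2}
  - {id: 2C1, kind: corridor, floor: 2}
  - {id: 2C2, kind: corridor, floor: 2}
  - {id: 2C3, kind: corridor, floor: 2}
  - {id: Stairs, kind: stairs, floor: both}

beacons:
  - {id: 1R1, area: 1R1, note: above room door}
  - {id: 1R2, area: 1R2, note: above room door}
  - {id: 1R3, area: 1R3, note: above room door}
  - {id: 1S1a, area: 1S1, note: social area, wall A}
  - {id: 1S1b, area: 1S1, note: social area, opposing wall}
  - {id: 1C1a, area: 1C1, note: long corridor, straight passage}
  - {id: 1C1b, area: 1C1, note: long corridor, after direction change}
  - {id: 1C2, area: 1C2}
  - {id: 1C3, area: 1C3}
  - {id: 2R1, area: 2R1, note: above room door}
  - {id: 2R2, area: 2R2, note: above room door}
  - {id: 2S1a, area: 2S1, note: social area, wall A}
  - {id: 2S1b, area: 2S1, note: social area, opposing wall}
  - {id: 2C1, area: 2C1}
  - {id: 2C2, area: 2C2}
  - {id: 2C3, area: 2C3}
  - {id: Stairs, area: Stairs, note: same beacon serves both floors}

edges:
  - {between: [1R1, 1C1], distance: 24}
  - {between: [1R2, 1C1], distance: 22}
  - {between: [1S1, 1C1], distance: 26}
  - {between: [1S1, 1C2], distance: 26}
  - {between: [1C1, 1C2], distance: 30}
  - {between: [1C2, 1R3], distance: 22}
  - {between: [1C2, 1C3], distance: 28}
  - {between: [1C3, Stairs], distance: 24}
  - {between: [Stairs, 2C1], distance: 24}
  - {between: [2C1, 2R1], distance: 22}
  - {between: [2C1, 2C2], distance: 28}
  - {between: [2C2, 2R2], distance: 22}
  - {between: [2C2, 2C3], distance: 24}
  - {between: [2C2, 2S1], distance: 24}
  - {between: [2C3, 2S1], distance: 22}
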