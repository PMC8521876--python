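# 16-sensor pressure-insole layout.
# Foot frame: origin at heel center, +x toward the toes, +y toward the
# medial side of the left foot (mirrored for the right). Units: mm.
# Clusters drive gait-event detection: rearfoot load marks heel contact,
# forefoot load marks push-off.
left:
  p00: {x: 15,  y: -15, cluster: rearfoot}
  p01: {x: 15,  y: 15,  cluster: rearfoot}
  p02: {x: 30,  y: -20, cluster: rearfoot}
  p03: {x: 30,  y: 20,  cluster: rearfoot}
  p04: {x: 30,  y: 0,   cluster: rearfoot}
  p05: {x: 80,  y: -25, cluster: midfoot}
  p06: {x: 80,  y: 25,  cluster: midfoot}
  p07: {x: 110, y: -25, cluster: midfoot}
  p08: {x: 110, y: 25,  cluster: midfoot}
  p09: {x: 150, y: -30, cluster: forefoot}
  p10: {x: 150, y: 0,   cluster: forefoot}
  p11: {x: 150, y: 30,  cluster: forefoot}
  p12: {x: 180, y: -25, cluster: forefoot}
  p13: {x: 180, y: 25,  cluster: forefoot}
  p14: {x: 210, y: -10, cluster: forefoot}
  p15: {x: 210, y: 10,  cluster: forefoot}
right:
  p00: {x: 15,  y: 15,  cluster: rearfoot}
  p01: {x: 15,  y: -15, cluster: rearfoot}
  p02: {x: 30,  y: 20,  cluster: rearfoot}
  p03: {x: 30,  y: -20, cluster: rearfoot}
  p04: {x: 30,  y: 0,   cluster: rearfoot}
  p05: {x: 80,  y: 25,  cluster: midfoot}
  p06: {x: 80,  y: -25, cluster: midfoot}
  p07: {x: 110, y: 25,  cluster: midfoot}
  p08: {x: 110, y: -25, cluster: midfoot}
  p09: {x: 150, y: 30,  cluster: forefoot}
  p10: {x: 150, y: 0,   cluster: forefoot}
  p11: {x: 150, y: -30, cluster: forefoot}
  p12: {x: 180, y: 25,  cluster: forefoot}
  p13: {x: 180, y: -25, cluster: forefoot}
  p14: {x: 210, y: 10,  cluster: forefoot}
  p15: {x: 210, y: -10, cluster: forefoot}
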