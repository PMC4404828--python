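# Default multivariate concentric square field (MCSF) arena.
#
# The outer field is 100 x 100 cm and contains a 70 x 70 cm central field;
# the central circle (CTRCI, diameter 22 cm) sits in the middle of the
# center.  Only those three dimensions are published for the apparatus; the
# 15-cm frame between the central field and the outer walls, and the way it
# is split into corridors A-C, the dark corner room (DCR), the hurdle, the
# slope, the bridge entrance (BE) and the bridge, are ASSUMPTIONS of this
# config, chosen to give a plausible planar layout with the documented
# connectivity (the DCR is reachable only through corridor A; the bridge is
# reached via slope and bridge entrance).  Elevation of hurdle/slope/bridge
# is ignored: tracking is 2-D overhead video.
#
# Coordinates: origin at the arena's lower-left corner, x right, y up, cm.
# rect geometry is [x0, y0, x1, y1]; circle is [cx, cy, radius].
version: 1
arena_size: [100.0, 100.0]
session_duration: 1800.0
zones:
  - zone_id: center
    display_name: center
    geometry: {rect: [15.0, 15.0, 85.0, 85.0]}
    light_lux: [0.0, 25.0]
  - zone_id: ctrci
    display_name: central circle
    geometry: {circle: [50.0, 50.0, 11.0]}
    parent_zone: center
    light_lux: [30.0, 35.0]
    role_tags: [risk]
  - zone_id: corr_a
    display_name: corridor A
    geometry: {rect: [0.0, 15.0, 15.0, 85.0]}
    light_lux: [0.0, 20.0]
    role_tags: [corridor]
  - zone_id: corr_b
    display_name: corridor B
    geometry: {rect: [0.0, 0.0, 100.0, 15.0]}
    light_lux: [0.0, 20.0]
    role_tags: [corridor]
  - zone_id: corr_c
    display_name: corridor C
    geometry: {rect: [85.0, 15.0, 100.0, 85.0]}
    light_lux: [0.0, 20.0]
    role_tags: [corridor]
  - zone_id: dcr
    display_name: dark corner room
    geometry: {rect: [0.0, 85.0, 15.0, 100.0]}
    light_lux: [0.0, 1.0]
    role_tags: [shelter]
  - zone_id: hurdle
    display_name: hurdle
    geometry: {rect: [15.0, 85.0, 55.0, 100.0]}
    light_lux: [0.0, 20.0]
  - zone_id: slope
    display_name: slope
    geometry: {rect: [55.0, 85.0, 75.0, 100.0]}
    role_tags: [transit]
  - zone_id: be
    display_name: bridge entrance
    geometry: {rect: [75.0, 85.0, 85.0, 100.0]}
    role_tags: [transit]
  - zone_id: bridge
    display_name: bridge
    geometry: {rect: [85.0, 85.0, 100.0, 100.0]}
    light_lux: [600.0, 850.0]
    role_tags: [risk]
adjacency:
  - [center, ctrci]
  - [center, corr_a]
  - [center, corr_b]
  - [center, corr_c]
  - [corr_a, corr_b]
  - [corr_b, corr_c]
  - [corr_a, dcr]
  - [corr_a, hurdle]
  - [hurdle, slope]
  - [slope, be]
  - [be, bridge]
aggregates:
  tot_corr: [corr_a, corr_b, corr_c]
  arena: [center, ctrci, corr_a, corr_b, corr_c, dcr, hurdle, slope, be, bridge]
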