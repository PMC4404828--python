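# Novel cage test ethogram: individual behaviors grouped by coping-style
# functional category.  Session duration 300 s.
test_type: novel_cage
session_duration: 300.0
categories:
  proactive_coping:
    stretched_approach: Walking with a flat body posture stretched and close to the floor
    sap: Stretched attend posture - forward stretch of the neck/front body, then retract
    grooming: Scratching, shaking, wiping or licking body parts
  reactive_coping:
    freezing: Sudden suppression of movements
    motionless: Sitting or lying without suppression of movements
  exploratory_activity:
    free_rearing: Standing on hind legs
    investigating: Exploring the floor, cage walls or air through olfactory activity
  locomotor_activity:
    wall_rearing: Standing on hind legs with forepaws leaning against a wall
    walking: Locomotor behavior with normal body posture
standalone: {}
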