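# Default functional-category map for the trend analysis.
#
# Each entry is [parameter, inverse]; inverse: true means low raw values
# indicate high expression of the category (e.g. a short mean corridor
# visit indicates high general activity), so the ranking order is reversed
# before summing.
general_activity:
  - [TOTAL_ACT, false]
  - [FRQ_tot_corr, false]
  - [DURFRQ_tot_corr, true]
  - [FRQ_center, false]
  - [DIST_arena, false]
exploratory_activity:
  - [DUR_tot_corr, true]
  - [DUR_center, true]
  - [DUR_hurdle, false]
  - [rearings, false]
  - [nose_pokes, false]
shelter_seeking:
  - [FRQ_dcr, false]
  - [DUR_dcr, false]
  - [DURFRQ_dcr, false]
risk_assessment:
  - [saps, false]
  - [DURFRQ_slope, false]
  - [DURFRQ_be, false]
risk_taking:
  - [FRQ_bridge, false]
  - [DUR_bridge, false]
  - [DURFRQ_bridge, false]
  - [FRQ_ctrci, false]
  - [DUR_ctrci, false]
  - [DURFRQ_ctrci, false]
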