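# Drinking-water guideline registry: WHO, US EPA and the Bangladesh
# Drinking Water Standard (Environmental Conservation Rules).
# exceed_mode semantics: above_upper -> value > upper; outside_range ->
# value < lower or value > upper.  The BDWS iron rule states an acceptable
# band 0.3-1.0 mg/L; its exceedance accounting uses the upper bound.
- {authority: WHO,   parameter: ph,  lower: 6.5, upper: 8.5,  exceed_mode: outside_range}
- {authority: USEPA, parameter: ph,  lower: 6.5, upper: 8.5,  exceed_mode: outside_range}
- {authority: BDWS,  parameter: ph,  lower: 6.5, upper: 8.5,  exceed_mode: outside_range}
- {authority: WHO,   parameter: ec,  upper: 250,              exceed_mode: above_upper}
- {authority: WHO,   parameter: tds, lower: 600, upper: 1000, exceed_mode: above_upper}
- {authority: USEPA, parameter: tds, upper: 500,              exceed_mode: above_upper}
- {authority: BDWS,  parameter: tds, upper: 1000,             exceed_mode: above_upper}
- {authority: WHO,   parameter: fe,  upper: 0.3,              exceed_mode: above_upper}
- {authority: USEPA, parameter: fe,  upper: 0.3,              exceed_mode: above_upper}
- {authority: BDWS,  parameter: fe,  lower: 0.3, upper: 1.0,  exceed_mode: above_upper}
- {authority: WHO,   parameter: as,  upper: 0.01,             exceed_mode: above_upper}
- {authority: USEPA, parameter: as,  upper: 0.01,             exceed_mode: above_upper}
- {authority: BDWS,  parameter: as,  upper: 0.05,             exceed_mode: above_upper}
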