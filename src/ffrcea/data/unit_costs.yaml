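# Unit costs, 2014 GBP. `se` present => gamma-distributed in the PSA,
# absent => fixed. Sources: national procurement, BNF, NHS reference costs,
# ISD Scotland, NICE clinical guidelines.
#
# The pressure wire is entered at its effective per-wire cost (279/1.03 =
# 270.87), the value consistent with the reported mean wire cost per FFR
# patient; the 2700 list price is retained as `pressure_wire_list` for
# sensitivity analyses.

# Equipment
guiding_catheter: {mean: 200.0}
guidewire: {mean: 200.0}
pressure_wire: {mean: 270.87}
pressure_wire_list: {mean: 2700.0}
adenosine_vial: {mean: 120.0}
balloon: {mean: 500.0}
des_stent: {mean: 2900.0}
bms_stent: {mean: 900.0}
tirofiban: {mean: 242.0, se: 69.0, dist: gamma}       # average GBP per treated patient
bivalirudin: {mean: 625.0, se: 48.0, dist: gamma}     # average GBP per treated patient
clopidogrel_month: {mean: 2.0}

# Procedures
cabg: {mean: 5041.0, se: 313.0, dist: gamma}
echo: {mean: 128.0, se: 26.0, dist: gamma}
oct: {mean: 1020.0, se: 204.0, dist: gamma}
ivus: {mean: 540.0, se: 108.0, dist: gamma}
xray: {mean: 18.0, se: 4.0, dist: gamma}

# Hospitalisation
cathlab_hour: {mean: 1681.0, se: 301.0, dist: gamma}
ccu_day: {mean: 1492.0, se: 60.0, dist: gamma}
itu_day: {mean: 2288.0, se: 458.0, dist: gamma}
ward_day: {mean: 303.0, se: 17.0, dist: gamma}

# In-hospital event costs
severe_bleed: {mean: 222.0, se: 3.0, dist: gamma}
stroke_inhospital: {mean: 2709.0, se: 129.0, dist: gamma}
mi_inhospital: {mean: 1492.0, se: 76.0, dist: gamma}

# Index-year event costs
rehospitalisation: {mean: 2261.0, se: 452.0, dist: gamma}
revascularisation: {mean: 2477.0, se: 63.0, dist: gamma}
mi_event: {mean: 2261.0, se: 452.0, dist: gamma}
mi_index_year: {mean: 3228.0, se: 215.0, dist: gamma}
stroke_index_year: {mean: 16926.0, se: 428.0, dist: gamma}
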