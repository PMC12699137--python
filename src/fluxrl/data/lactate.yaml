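# Lactate fermentation by engineered E. coli (delta-adhE, delta-ackA-pta)
# with green-light-inducible F1-ATPase expression (CcaS/CcaR).  ATP
# wasting raises glucose uptake and lactate flux at the cost of growth.
# S, X, L in g/L; ATPase level E in virtual units per gram biomass (VU/g).
version: 1
name: lactate
parameters:
  qSmax: {value: 1.731,     unit: "g/(g h)",  meaning: "maximum specific glucose uptake rate"}
  kS:    {value: 5.340e-7,  unit: "g/L",      meaning: "glucose half-saturation of uptake"}
  kSV:   {value: 1.053e-6,  unit: "VU/g",     meaning: "ATPase half-saturation of uptake boost"}
  n1:    {value: 1.000e-2,  unit: "-",        meaning: "Hill exponent, uptake boost"}
  mS:    {value: 1.232e-6,  unit: "g/(g h)",  meaning: "maintenance substrate demand"}
  kXV:   {value: 2.605e-4,  unit: "VU/g",     meaning: "ATPase half-saturation of growth suppression"}
  n2:    {value: 1.028e-1,  unit: "-",        meaning: "Hill exponent, growth suppression"}
  YXS:   {value: 1.083e-1,  unit: "g/g",      meaning: "biomass yield on glucose"}
  YLX:   {value: 2.204,     unit: "g/g",      meaning: "growth-associated lactate yield"}
  mL:    {value: 1.910,     unit: "g/(g h)",  meaning: "non-growth-associated lactate rate"}
  # kLS is not part of the source kinetic model; it gates lactate
  # production off under substrate starvation.
  kLS:   {value: 1.0e-10,   unit: "g/L",      meaning: "substrate gate of lactate synthesis"}
  kLV:   {value: 10.02,     unit: "VU/g",     meaning: "ATPase half-saturation of lactate boost"}
  n3:    {value: 10.0,      unit: "-",        meaning: "Hill exponent, lactate boost"}
  qE0:   {value: 1.000e-6,  unit: "VU/(g h)", meaning: "basal ATPase expression rate"}
  qEmax: {value: 10.0,      unit: "VU/(g h)", meaning: "maximum light-induced ATPase expression rate"}
  kl:    {value: 3.729e2,   unit: "umol/(m2 s)", meaning: "light half-saturation of expression"}
  n4:    {value: 4.718,     unit: "-",        meaning: "Hill exponent, light induction"}
  kd:    {value: 0.988,     unit: "1/h",      meaning: "first-order ATPase decay rate"}
initial_conditions:
  "S": 4.0
  "X": 0.075
  "L": 0.0
  "E": 0.0
input:
  unit: "umol/(m2 s) green-light photon flux"
  lower: 0.0
  upper: 873.0
  static_baseline: 873.0
randomization_defaults:
  initials: ["S", "X", "L", "E"]
  parameters: ["qEmax"]
solver: LSODA
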