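# Fatty-acid biosynthesis in engineered E. coli with inducible
# acetyl-CoA carboxylase (ACC) expression under LacI repression.
# All dynamic states are normalized dimensionless variables; HX / HP
# convert biomass and product to relative OD600 units and g/L.
version: 1
name: fatty_acid
parameters:
  kX:    {value: 0.4639,  unit: "1/h",  meaning: "maximum specific growth-rate constant"}
  kE:    {value: 0.6088,  unit: "1/h",  meaning: "maximum ACC expression rate"}
  kM:    {value: 0.4314,  unit: "1/h",  meaning: "malonyl-CoA synthesis rate constant"}
  kP:    {value: 0.4314,  unit: "1/h",  meaning: "fatty-acid synthesis rate constant"}
  kR1:   {value: 17.77,   unit: "1/h",  meaning: "constitutive LacI expression rate"}
  mu_d:  {value: 0.00763, unit: "1/h",  meaning: "biomass decay rate"}
  TXmax: {value: 0.5081,  unit: "-",    meaning: "maximum growth-toxicity factor"}
  Etox:  {value: 1.0,     unit: "-",    meaning: "ACC toxicity threshold for product formation"}
  dE:    {value: 0.1131,  unit: "1/h",  meaning: "ACC degradation rate"}
  dR:    {value: 1.386,   unit: "1/h",  meaning: "LacI degradation rate"}
  KTX:   {value: 0.4587,  unit: "-",    meaning: "half-saturation of growth toxicity in E"}
  KTP:   {value: 0.3445,  unit: "-",    meaning: "half-saturation of product toxicity in E - Etox"}
  KR0:   {value: 1.0,     unit: "-",    meaning: "repression half-saturation in free LacI"}
  KI:    {value: 17.61,   unit: "uM",   meaning: "inducer half-saturation (IPTG-equivalent)"}
  KSP:   {value: 0.01397, unit: "-",    meaning: "substrate half-saturation of product synthesis"}
  nTX:   {value: 2.798,   unit: "-",    meaning: "Hill exponent, growth toxicity"}
  nTP:   {value: 1.137,   unit: "-",    meaning: "Hill exponent, product toxicity"}
  nR:    {value: 0.5576,  unit: "-",    meaning: "Hill exponent, LacI repression"}
  nI:    {value: 1.034,   unit: "-",    meaning: "Hill exponent, inducer binding"}
  HX:    {value: 1.688,   unit: "-",    meaning: "dimensionless biomass to relative OD600"}
  HP:    {value: 0.4843,  unit: "g/L",  meaning: "dimensionless product to g/L"}
initial_conditions:
  # The nominal initial glucose is tied to the initial biomass,
  # S0 = 1 - X0*; under domain randomization S0 is then perturbed as an
  # initial condition in its own right around that nominal value.
  "X*": 0.1107
  "E": 0.0
  "M": 0.0
  "R": 0.002
  "P*": 0.0
input:
  unit: "uM IPTG-equivalent"
  lower: 0.0
  upper: 1000.0
  static_baseline: 40.0
randomization_defaults:
  initials: ["S", "X*", "E", "M", "R", "P*"]
  parameters: ["kE", "kR1"]
solver: RK45
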