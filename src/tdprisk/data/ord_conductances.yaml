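# Versioned conductance/permeability configuration for the paced ventricular
# myocyte model (endocardial baseline) and the CiPA in-silico rescaling of
# the five repolarization-critical currents (Dutta et al. optimization).
model_version: ord2011-dutta2017-v1
# Baseline maximal conductances (mS/uF) / permeabilities (cm/s) of the seven
# drug-targetable currents, endocardial cell.
base_conductances:
  INa: 75.0
  INaL: 0.0075
  ICaL: 1.0e-4
  IKr: 0.046
  IKs: 0.0034
  IK1: 0.1908
  Ito: 0.02
# Multiplicative rescaling applied to five currents (CiPA-optimized model).
cipa_rescale:
  IKr: 1.013
  IKs: 1.870
  IK1: 1.698
  ICaL: 1.007
  INaL: 2.661
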