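# Frozen default parameterization of the PKC life-cycle model.
# Produced by the staged deterministic calibration in pkclife.calibrate
# (see docs/methods.md for the anchor set); do not edit by hand.
#
# Units: first-order constants s^-1; second-order constants per ng/ml per s
# (k15 per nM per s); clamped levels dimensionless model units; mRNA0 ng/ml.
k1: 1.0
k2: 0.001
k3: 0.1603
k4: 0.01
k5: 0.001
k6: 0.05
k7: 0.01
k8: 0.001
k9: 1.0e-05
k10: 0.001
k11: 0.01
k12: 0.00127
k13: 0.001
k14: 0.01
k15: 400.0
k16: 74.69114649627403
k17: 0.01942810081489849
k18: 3.5e-05
k19: 1.0e-06
k20: 8.235500314278398e-06
lam1: 0.001
lam2: 0.0002
lam3: 0.001
lam4: 1.3333333333e-06
lam5: 0.0
T: 1.0
PDK1: 1.0
MTORC2: 1.0
PHLPP: 1.0
HSP70: 1.0
mRNA0: 1.0
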