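# Default radiobiological tissue parameters for breast-plan evaluation.
# alpha_beta : linear-quadratic fractionation-sensitivity ratio (Gy)
# a          : Niemierko EUD volume-effect exponent (targets: a < 0)
# gamma      : maximum normalized slope of the Poisson-LQ dose-response curve
# d50        : dose giving 50% response probability (Gy)
# m          : LKB slope parameter
# n          : LKB volume-effect parameter
breast_ptv:
  alpha_beta: 4.0
  a: -7.2
  gamma: 1.3
  d50: 30.89
heart:
  alpha_beta: 4.0
  d50: 48.0
  m: 0.1
  n: 0.35
lung:
  alpha_beta: 4.0
  d50: 37.6
  m: 0.35
  n: 0.87
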