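# Water-to-fat conversion model defaults.
#
# logit: logit(P_fat) = alpha0 + alpha1 * x + x * eps, x = P_H2O / (1 - P_H2O),
# eps ~ N(0, sigma2).  Point values are the fit to pooled carcass data
# (fat decreases with water, so alpha1 < 0).
logit:
  alpha0: 0.86
  alpha1: -1.6
  sigma2: 0.09
# Linear gray-seal rule: fat mass = total mass - 1.37 * TBW.
iverson:
  coefficient: 1.37
# Guinea-pig hydration constants: water fraction of adipose (w_adipose) and
# of non-adipose lean tissue (w_lean), fat fraction of adipose tissue
# (f_adipose), each a beta-distributed proportion; labeled-water proportion
# water is multiplied by 0.967 before use to remove the tracer's known
# high bias relative to desiccation.
pace_rathbun:
  w_adipose: {mean: 0.151, sd: 0.02}
  w_lean: {mean: 0.732, sd: 0.01}
  f_adipose: {mean: 0.854, sd: 0.02}
  water_bias_adjustment: 0.967
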