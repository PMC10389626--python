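# Published final-model coefficients (log odds), log-logistic family.
# Competing-risks mixture model for 1-year survivors of esophagectomy;
# age enters as (age - 65.1) / 10.
family = loglogistic
alpha.intercept = -1.26
alpha.age = 0.28
alpha.scc = 0.58
alpha.chemo = 0.45
alpha.stage_ii = 1.57
alpha.stage_iii = 2.25
alpha.stage_iv = 2.37
alpha.margin = 1.62
eta.intercept = 2.67
eta.age = -0.15
eta.female = 0.29
eta.education_gt12 = 0.38
eta.scc = -0.26
eta.stage_iii = -0.56
eta.stage_iv = -0.98
eta.margin = -0.62
eta.reoperation = -0.46
phi.intercept = -0.76
gamma.intercept = -2.20
rho.intercept = -0.42
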