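# Robustness conditions: 100 strong instruments of varying strength, 30% of
# them invalid with directional pleiotropy alpha ~ N(0.05, 0.01^2).  Used to
# compare weighted-median and IVW bias and to measure Egger-intercept power.
m_variants: 100
n_blocks: 100
ld_rho: 0.0
n_exposure: 200000
n_outcome: 85844
theta: 0.1
n_instruments: 100
gamma_mean: 0.1
gamma_sd: 0.05
prop_invalid: 0.3
alpha_mean: 0.05
alpha_sd: 0.01
p_palindromic: 0.0
p_allele_swap: 0.3
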