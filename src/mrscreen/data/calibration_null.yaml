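# Null-effect calibration conditions: 30 independent strong-ish instruments,
# realistic GWAS sample sizes, no causal effect, no pleiotropy.  Used to check
# IVW type-I error, Cochran's Q uniformity, and Egger-intercept calibration.
m_variants: 30
n_blocks: 30
ld_rho: 0.0
n_exposure: 26333
n_outcome: 85844
theta: 0.0
n_instruments: 30
gamma_mean: 0.0
gamma_sd: 0.08
prop_invalid: 0.0
alpha_mean: 0.0
alpha_sd: 0.0
p_palindromic: 0.0
p_allele_swap: 0.3
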