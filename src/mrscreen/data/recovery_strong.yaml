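# Effect-recovery conditions: theta = 0.2 with uniformly strong instruments
# (large exposure GWAS, per-SNP F in the hundreds) so that the no-measurement-
# error assumption behind the first-order Wald-ratio SE effectively holds and
# coverage reflects estimator calibration.
m_variants: 30
n_blocks: 30
ld_rho: 0.0
n_exposure: 200000
n_outcome: 85844
theta: 0.2
n_instruments: 30
gamma_mean: 0.1
gamma_sd: 0.02
prop_invalid: 0.0
alpha_mean: 0.0
alpha_sd: 0.0
p_palindromic: 0.0
p_allele_swap: 0.3
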