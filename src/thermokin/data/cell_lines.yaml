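# Published thermal-injury coefficients for murine pancreatic cancer
# (KPC, Pan02) and fibroblast (STO) cell lines, estimated from 24 h
# post-hyperthermia viability after water-bath exposures at 42.5-50 degC.
#   activation_energy   Ea, J/mol
#   ln_frequency_factor ln A, A in 1/s
#   delay_intercept_b   b of the shoulder line t_d = b - m*T, seconds
#   delay_slope_m       m, s/K
#   r_cem               fitted per-degree isoeffect factor above 43 degC
gas_constant: 8.314
cell_lines:
  KPC:
    activation_energy: 383112.0
    ln_frequency_factor: 137.63
    delay_intercept_b: 254920.0
    delay_slope_m: 800.0
    r_cem: 0.588
  Pan02:
    activation_energy: 427712.0
    ln_frequency_factor: 153.63
    delay_intercept_b: 127460.0
    delay_slope_m: 400.0
    r_cem: 0.596
  STO:
    activation_energy: 455630.0
    ln_frequency_factor: 164.79
    delay_intercept_b: 127460.0
    delay_slope_m: 400.0
    r_cem: 0.607
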