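# nsad isotope table, version 1
# b_coh_far: real coherent scattering length far from resonance (fm); for
#   resonant nuclei this is the potential-scattering term R of the
#   single-level Breit-Wigner expression.
# sigma_inc: incoherent cross section (barn), wavelength independent.
# sigma_abs_thermal: 2200 m/s (1.798 A) absorption cross section (barn) for
#   1/v absorbers; resonant isotopes compute absorption from the resonance
#   instead and leave this 0.
# Resonance columns (blank when the isotope has no tabulated resonance):
#   E_r (meV), Gamma (total width, meV), Gamma_n (neutron re-emission width
#   at E_r, meV), g (spin statistical factor (2J+1)/(2(2I+1))).
label,b_coh_far,sigma_inc,sigma_abs_thermal,E_r_meV,Gamma_meV,Gamma_n_meV,g
H,-3.7390,80.27,0.3326,,,,
D,6.6710,2.05,0.000519,,,,
C,6.6460,0.001,0.0035,,,,
N,9.3600,0.50,1.90,,,,
O,5.8030,0.0008,0.00019,,,,
S,2.8470,0.007,0.53,,,,
P,5.1300,0.005,0.172,,,,
Cd113,6.8,0.3,0.0,178.0,114.137,0.637,0.75
Sm149,7.2,0.0,0.0,97.3,61.033,0.533,0.5625
Eu151,7.2,3.1,0.0,321.0,95.9,0.90,0.5833
Gd157,7.3,0.0,0.0,31.4,106.47,0.47,0.625
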