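# Ground-truth methylation profiles per experimental condition.
#
# Each condition describes per-strand target-site methylation frequency as a
# function of the PAM-to-CpG gap length g:
#
#   p_s(g) = baseline                                   outside [g_min, g_max]
#   p_s(g) = clip(A_s * exp(kappa*(cos(2*pi*(g - peak_s)/T) - 1)),
#                 baseline, 1)                          inside the support
#
# s is 'cis' (the PAM/protospacer strand) or 'trans' (the sgRNA-complementary
# strand).  Amplitudes at the optimal gap and the support window are anchored
# to measured per-strand frequencies; peak positions, angular sharpness kappa
# and cis-strand amplitudes for sparsely measured conditions are model choices
# documented in docs/methods.md.
#
# offtarget_median parameterises the Beta baseline used for the 241 non-target
# CpG dyads (median per-cytosine frequency); offtarget_dispersion is the Beta
# alpha shape (larger = tighter around the median).

linker4:
  linker_length: 4
  period_T: 11.0
  peak_gap: {cis: 14.0, trans: 11.0}
  amplitude: {cis: 0.010, trans: 0.524}
  kappa: 3.0
  support: [9, 14]
  baseline: 0.0060
  offtarget_median: 0.0060
  offtarget_dispersion: 1.0

linker15:
  linker_length: 15
  period_T: 11.0
  peak_gap: {cis: 14.0, trans: 11.0}
  amplitude: {cis: 0.250, trans: 0.367}
  kappa: 1.0
  support: [8, 26]
  baseline: 0.0062
  offtarget_median: 0.0062
  offtarget_dispersion: 1.0

linker25:
  linker_length: 25
  period_T: 11.0
  peak_gap: {cis: 14.0, trans: 11.0}
  amplitude: {cis: 0.300, trans: 0.550}
  kappa: 0.8
  support: [8, 36]
  baseline: 0.0059
  offtarget_median: 0.0059
  offtarget_dispersion: 1.0

# Affinity-weakening MC-domain mutants (15-aa linker backbone).  Off-target
# baselines are many-fold lower than the linker series.

Y305F:
  linker_length: 15
  period_T: 11.0
  peak_gap: {cis: 14.0, trans: 11.0}
  amplitude: {cis: 0.020, trans: 0.300}
  kappa: 4.0
  support: [9, 13]
  baseline: 0.0010
  offtarget_median: 0.0010
  offtarget_dispersion: 1.0

T313A:
  linker_length: 15
  period_T: 11.0
  peak_gap: {cis: 14.0, trans: 11.0}
  amplitude: {cis: 0.020, trans: 0.300}
  kappa: 4.0
  support: [9, 13]
  baseline: 0.0010
  offtarget_median: 0.0010
  offtarget_dispersion: 1.0

# Single-replica mutants were measured only at gap 12; their profiles are
# anchored there (peak placed at the measured gap).

S291F:
  linker_length: 15
  period_T: 11.0
  peak_gap: {cis: 12.0, trans: 12.0}
  amplitude: {cis: 0.022, trans: 0.210}
  kappa: 2.0
  support: [9, 15]
  baseline: 0.0010
  offtarget_median: 0.0010
  offtarget_dispersion: 1.0

S317A:
  linker_length: 15
  period_T: 11.0
  peak_gap: {cis: 12.0, trans: 12.0}
  amplitude: {cis: 0.035, trans: 0.206}
  kappa: 2.0
  support: [9, 15]
  baseline: 0.0010
  offtarget_median: 0.0010
  offtarget_dispersion: 1.0
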