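# Amide (triglycine N2) 2D run: 64 rotor-synchronised t1 increments,
# States detection; process with `quadspy spectrum-2d`.
system:
  preset: triglycine_amide
  mas_rate_khz: 25.0
experiment:
  tau_n_ms: 2.0
  nu1_n_khz: 50.0
  selection: SQ
  t1_increments: 64
  dt1_rotor_periods: 1
powder:
  size: 1154
processing:
  lb1_hz: 100.0
  zerofill: 1024
output_dir: quadspy_results
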