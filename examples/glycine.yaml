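# Glycine amine working point: 2 ms, 35 kHz CW 14N pulse at 25 kHz MAS.
system:
  preset: glycine_amine
  mas_rate_khz: 25.0
experiment:
  tau_n_ms: 2.0
  nu1_n_khz: 35.0
  offset_n_khz: 0.0
  selection: SQ
powder:
  size: 1154
processing:
  lb_hz: 30.0
  zerofill: 1024
output_dir: quadspy_results
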