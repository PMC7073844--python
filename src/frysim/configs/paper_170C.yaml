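# Constant-temperature frying: 170 degC bath, 9 min, default strip parameters.
schema: 1
schedule:
  T_fry: 443.15
  t_end: 540.0
  f: 1.0
numerics:
  snapshot_times: [540.0]
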