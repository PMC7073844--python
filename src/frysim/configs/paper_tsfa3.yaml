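# Temperature-step frying: 170 degC for 3 min, then 150.0 degC to 9 min.
# f multiplies the absolute bath temperature: 443.15 K * 0.95489 = 423.16 K.
schema: 1
schedule:
  T_fry: 443.15
  t_H: 180.0
  f: 0.95489
  t_end: 540.0
numerics:
  snapshot_times: [540.0]
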