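# Physiology for a 60 kg human. Volume/flow fractions are standard reference
# compilation values; the liver fraction (2.6% -> 1560 g) is fixed so that the
# scaled and unscaled Vmax values in the shipped compound files reconcile.
species: human
body_weight: 60.0          # kg
volume_fractions:          # fraction of body weight; remainder unperfused
  liver: 0.026
  kidney: 0.004
  fat: 0.214
  richly: 0.05
  slowly: 0.52
  blood: 0.079
flow_fractions:            # fraction of cardiac output, sums to 1
  liver: 0.227
  kidney: 0.175
  fat: 0.052
  richly: 0.246
  slowly: 0.30
cardiac_output: 310.0      # L/h (15 * BW^0.74)
gfr: 1.8                   # mL/min/kg BW
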