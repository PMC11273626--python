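# Physiology for a 0.25 kg rat. Volume/flow fractions are standard reference
# compilation values; the liver fraction (3.4% -> 8.5 g) is fixed so that the
# scaled and unscaled Vmax values in the shipped compound files reconcile.
species: rat
body_weight: 0.25          # kg
volume_fractions:          # fraction of body weight; remainder unperfused
  liver: 0.034
  kidney: 0.007
  fat: 0.07
  richly: 0.05
  slowly: 0.676
  blood: 0.074
flow_fractions:            # fraction of cardiac output, sums to 1
  liver: 0.183
  kidney: 0.141
  fat: 0.07
  richly: 0.27
  slowly: 0.336
cardiac_output: 5.38       # L/h (15 * BW^0.74)
gfr: 5.2                   # mL/min/kg BW
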