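# Human compound parameters.
# - Metabolic pathway Vmax/Km pairs are the measured microsomal/S9 values
#   scaled to a whole liver of 1560 g.
# - The metabolite's hepatic intrinsic clearance is 0 in humans (reported
#   hepatocyte data show no depletion); it is eliminated renally only.
# - Tissue:blood partition coefficients are PLACEHOLDER values; replace with
#   compound-specific predictions when available.
parent:
  name: aloe-emodin
  molar_mass: 270.24
  bpr: 0.55
  fup: 0.092
  ka: 0.14                 # 1/h
  fa: 0.36
  kb: 1.0
  partition:
    liver: 2.0
    kidney: 1.5
    richly: 1.5
    slowly: 1.0
    fat: 3.0
  pathways:
    - pathway: rhein_formation
      vmax_unscaled: 0.0786
      vmax_scaled: 294.0
      km: 16.9
      protein_source: microsomes
    - pathway: AEG1
      vmax_unscaled: 0.129
      vmax_scaled: 1459.0
      km: 11.4
      protein_source: s9
    - pathway: AEG2
      vmax_unscaled: 0.131
      vmax_scaled: 1477.0
      km: 9.78
      protein_source: s9
    - pathway: AEG3
      vmax_unscaled: 0.0961
      vmax_scaled: 1086.0
      km: 11.4
      protein_source: s9
metabolite:
  name: rhein
  molar_mass: 284.22
  bpr: 0.96
  fup: 0.91
  partition:
    liver: 1.0
    kidney: 1.0
    richly: 1.0
    slowly: 0.6
    fat: 0.3
  clint: 0.0
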