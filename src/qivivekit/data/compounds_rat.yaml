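# Rat compound parameters.
# - Metabolic pathway Vmax/Km pairs are the measured microsomal/S9 values
#   scaled to a whole liver of 8.5 g (unscaled Vmax in nmol/min/mg protein,
#   scaled Vmax in umol/h, Km in uM).
# - ka/Fa are pinned to the permeability-derived values; the alternative pair
#   fitted directly to oral profiles is available under absorption_alt.
# - Tissue:blood partition coefficients are PLACEHOLDER values (plausible for
#   a moderately lipophilic acid after blood/plasma-ratio correction); replace
#   with compound-specific predictions when available.
parent:
  name: aloe-emodin
  molar_mass: 270.24       # g/mol
  bpr: 0.55                # blood/plasma ratio (1 - hematocrit for an acid)
  fup: 0.092               # unbound fraction in plasma
  ka: 0.21                 # 1/h
  fa: 0.26                 # fraction absorbed
  kb: 1.0                  # 1/h biliary excretion from liver
  absorption_alt:          # alternative fitted pair, not the default
    ka: 4.0
    fa: 0.022
  partition:               # tissue:blood, placeholders
    liver: 2.0
    kidney: 1.5
    richly: 1.5
    slowly: 1.0
    fat: 3.0
  pathways:
    - pathway: rhein_formation
      vmax_unscaled: 0.472
      vmax_scaled: 11.1
      km: 4.31
      protein_source: microsomes
    - pathway: AEG1
      vmax_unscaled: 0.799
      vmax_scaled: 67.2
      km: 11.1
      protein_source: s9
    - pathway: AEG2
      vmax_unscaled: 0.214
      vmax_scaled: 18.0
      km: 9.91
      protein_source: s9
    - pathway: AEG3
      vmax_unscaled: 0.126
      vmax_scaled: 10.6
      km: 12.5
      protein_source: s9
metabolite:
  name: rhein
  molar_mass: 284.22       # g/mol
  bpr: 0.95
  fup: 0.91
  partition:               # tissue:blood, placeholders
    liver: 1.0
    kidney: 1.0
    richly: 1.0
    slowly: 0.6
    fat: 0.3
  clint: 0.264             # L/h whole-liver intrinsic clearance
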