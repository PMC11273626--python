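endpoint,bmcl10_parent_uM,bmcu10_parent_uM,bmcl10_metabolite_uM,bmcu10_metabolite_uM,rpf_reported
hepatotoxicity,7.3,18.6,6.3,13.0,1.20
nephrotoxicity,0.37,5.2,9.9,42.7,0.037
ros,0.1,53.5,0.16,14.6,0.63
nrf2,1.1,3.6,2.3,5.9,0.48
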