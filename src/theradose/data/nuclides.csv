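name,half_life_h,mean_electron_mev,mean_photon_mev
Cu-64,12.7006,0.121,0.187
Lu-177,159.46,0.147,0.033
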