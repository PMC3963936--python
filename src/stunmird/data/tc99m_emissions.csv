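# nuclide=Tc-99m half_life_h=6.0067
# Discrete per-decay emission lines for the isomeric decay of Tc-99m to Tc-99,
# compiled from the MIRD "Radionuclide Data and Decay Schemes" / ICRP Publication 107
# decay-data tabulations. Continuous Auger-cascade spectra are represented by their
# mean discrete lines (the listed lines carry >=99% of the emitted electron energy).
# Conversion-electron (CE) shells refer to the 2.17, 140.5 and 142.6 keV transitions.
# yields are emissions per nuclear transformation.
kind,energy_keV,yield
photon,140.511,0.885
photon,142.63,0.00023
photon,18.367,0.0366
photon,18.251,0.0191
photon,20.66,0.0124
photon,2.42,0.0082
electron,0.226,1.10
electron,1.63,0.746
electron,2.05,0.098
electron,2.13,0.198
electron,15.35,0.0149
electron,17.85,0.0055
electron,20.3,0.0007
electron,119.467,0.0879
electron,121.59,0.00305
electron,137.47,0.0107
electron,139.57,0.00255
electron,139.97,0.00187
electron,140.43,0.00038
electron,142.11,0.0005
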