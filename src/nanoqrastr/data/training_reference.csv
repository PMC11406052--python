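formula,EI_zebrafish,note
Cr2O3,44.72,observed response quoted in running text; full training table unpublished
Co3O4,-1.04,observed response quoted in running text; full training table unpublished
CeO2,2.56,observed response quoted in running text; full training table unpublished
TiO2,13.28,observed response quoted in running text; full training table unpublished
ZnO,42.72,observed response quoted in running text; full training table unpublished
In2O3,7.12,observed response quoted in running text; full training table unpublished
Al2O3,3.44,observed response quoted in running text; full training table unpublished
Mn2O3,17.2,observed response quoted in running text; full training table unpublished
WO3,,response not recoverable from the text (conflicting attribution); left blank
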