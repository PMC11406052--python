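formula,sum_alpha_sq,SE_LK,CVsim_LK,pred_EI,ad_status
Ag2O,544.29,8.58,0.73,128.34,out
Au2O,994.14,15.14,2.11,225.01,out
Au2O3,1036.20,15.14,2.11,232.33,out
BaO,32.83,9.87,0.58,47.63,in
BeO,1.77,10.01,0.57,43.14,in
Bi2O3,52.27,6.58,0.75,32.45,in
CaO,11.09,9.60,0.54,42.89,in
CdO,36.97,9.85,0.43,49.94,in
Co2O3,86.92,6.49,0.98,35.54,in
Ga2O3,52.02,6.58,0.73,32.63,in
GeO2,8.96,9.97,0.56,44.24,in
HfO2,58.68,9.93,0.68,51.40,in
HgO,66.10,8.65,0.33,49.92,in
IrO2,84.46,9.00,0.43,53.80,in
MgO,8.01,9.59,0.54,42.28,in
MnO2,20.19,9.99,0.54,46.52,iIn
Mo2O3,461.82,9.80,1.05,116.71,out
Nb2O3,440.58,9.22,0.87,112.16,out
OsO2,64.96,9.45,0.46,52.45,in
PbO,17.89,9.09,0.36,43.42,in
PbO2,20.79,9.14,0.35,44.33,in
PdO,0.52,9.58,0.52,41.21,in
PtO,247.43,10.63,1.34,80.54,out
PtO2,257.92,10.63,1.34,82.36,out
ReO2,63.36,8.74,0.28,50.52,in
Rh2O3,528.54,11.23,1.36,132.23,out
RuO2,130.19,8.92,0.85,56.79,in
Sc2O3,53.63,7.62,0.34,42.42,in
SrO,23.33,9.88,0.56,46.21,in
Ta2O3,230.74,9.62,1.00,76.16,in
TcO2,33.47,9.66,0.41,48.52,in
Tl2O,115.13,7.09,0.57,47.95,in
Tl2O3,129.73,7.12,0.51,51.25,in
V2O3,11.49,7.84,0.69,32.42,in
WO2,61.78,8.65,0.54,46.92,in
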