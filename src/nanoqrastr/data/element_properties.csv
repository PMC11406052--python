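symbol,Z,atomic_mass,chi_pauling,Zv_paper,Zv_standard,period,a0_pm,r_ion_pm,ox_state_for_r_ion,density_gcc,Ea_eV,I1_eV,source
O,8,15.999,3.44,6,6,2,60,126,-2,0.001429,1.461,13.618,CRC/Shannon curated
Be,4,9.012,1.57,2,2,2,105,59,2,1.85,0.0,9.323,CRC/Shannon curated
Mg,12,24.305,1.31,2,2,3,150,86,2,1.74,0.0,7.646,CRC/Shannon curated
Al,13,26.982,1.61,3,3,3,125,67.5,3,2.70,0.441,5.986,CRC/Shannon curated
Si,14,28.085,1.90,4,4,3,110,54,4,2.33,1.389,8.152,CRC/Shannon curated
Ca,20,40.078,1.00,2,2,4,180,114,2,1.55,0.025,6.113,CRC/Shannon curated
Sc,21,44.956,1.36,2,3,4,160,88.5,3,2.99,0.188,6.561,CRC/Shannon curated
Ti,22,47.867,1.54,2,4,4,140,74.5,4,4.51,0.079,6.828,CRC/Shannon curated
V,23,50.942,1.63,5,5,4,135,78,3,6.11,0.525,6.746,CRC/Shannon curated
Cr,24,51.996,1.66,1,6,4,140,75.5,3,7.19,0.666,6.767,CRC/Shannon curated
Mn,25,54.938,1.55,2,7,4,140,78.5,3,7.21,0.0,7.434,CRC/Shannon curated
Fe,26,55.845,1.83,2,8,4,140,78.5,3,7.87,0.163,7.902,CRC/Shannon curated
Co,27,58.933,1.88,2,9,4,135,75,3,8.90,0.661,7.881,CRC/Shannon curated
Ni,28,58.693,1.91,2,10,4,135,83,2,8.91,1.157,7.640,CRC/Shannon curated
Cu,29,63.546,1.90,1,1,4,135,87,2,8.96,1.236,7.726,CRC/Shannon curated
Zn,30,65.38,1.65,2,2,4,135,88,2,7.14,0.0,9.394,CRC/Shannon curated
Ga,31,69.723,1.81,3,3,4,130,76,3,5.91,0.301,5.999,CRC/Shannon curated
Ge,32,72.630,2.01,4,4,4,125,67,4,5.32,1.233,7.900,CRC/Shannon curated
Sr,38,87.62,0.95,2,2,5,200,132,2,2.64,0.048,5.695,CRC/Shannon curated
Y,39,88.906,1.22,2,3,5,180,104,3,4.47,0.307,6.217,CRC/Shannon curated
Zr,40,91.224,1.33,2,4,5,155,86,4,6.52,0.426,6.634,CRC/Shannon curated
Nb,41,92.906,1.60,1,5,5,145,86,3,8.57,0.916,6.759,CRC/Shannon curated
Mo,42,95.95,2.16,1,6,5,145,83,3,10.28,0.746,7.092,CRC/Shannon curated
Tc,43,98.0,1.90,2,7,5,135,78.5,4,11.50,0.55,7.280,CRC/Shannon curated
Ru,44,101.07,2.20,1,8,5,130,76,4,12.37,1.05,7.360,CRC/Shannon curated
Rh,45,102.906,2.28,1,9,5,135,80.5,3,12.41,1.142,7.459,CRC/Shannon curated
Pd,46,106.42,2.20,18,10,5,140,100,2,12.02,0.562,8.337,CRC/Shannon curated
Ag,47,107.868,1.93,1,1,5,160,129,1,10.49,1.302,7.576,CRC/Shannon curated
Cd,48,112.414,1.69,2,2,5,155,109,2,8.65,0.0,8.994,CRC/Shannon curated
In,49,114.818,1.78,3,3,5,155,94,3,7.31,0.384,5.786,CRC/Shannon curated
Sn,50,118.710,1.96,4,4,5,145,83,4,7.29,1.112,7.344,CRC/Shannon curated
Sb,51,121.760,2.05,5,5,5,145,90,3,6.68,1.046,8.608,CRC/Shannon curated
Ba,56,137.327,0.89,2,2,6,215,149,2,3.59,0.145,5.212,CRC/Shannon curated
La,57,138.905,1.10,2,3,6,195,117.2,3,6.16,0.47,5.577,CRC/Shannon curated
Ce,58,140.116,1.12,2,4,6,185,101,4,6.77,0.65,5.539,CRC/Shannon curated
Hf,72,178.486,1.30,2,4,6,155,85,4,13.31,0.017,6.825,CRC/Shannon curated
Ta,73,180.948,1.50,2,5,6,145,86,3,16.69,0.322,7.550,CRC/Shannon curated
W,74,183.84,2.36,2,6,6,135,74,6,19.25,0.816,7.864,CRC/Shannon curated
Re,75,186.207,1.90,2,7,6,135,77,4,21.02,0.15,7.834,CRC/Shannon curated
Os,76,190.23,2.20,2,8,6,130,77,4,22.59,1.078,8.438,CRC/Shannon curated
Ir,77,192.217,2.20,2,9,6,135,76.5,4,22.56,1.564,8.967,CRC/Shannon curated
Pt,78,195.084,2.28,1,10,6,135,76.5,4,21.45,2.128,8.959,CRC/Shannon curated
Au,79,196.967,2.54,1,1,6,135,99,3,19.30,2.309,9.226,CRC/Shannon curated
Hg,80,200.592,2.00,2,2,6,150,116,2,13.53,0.0,10.438,CRC/Shannon curated
Tl,81,204.38,1.62,3,3,6,190,102.5,3,11.85,0.377,6.108,CRC/Shannon curated
Pb,82,207.2,2.33,4,4,6,180,133,2,11.34,0.364,7.417,CRC/Shannon curated
Bi,83,208.980,2.02,5,5,6,160,117,3,9.78,0.942,7.286,CRC/Shannon curated
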