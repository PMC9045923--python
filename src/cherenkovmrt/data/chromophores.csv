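# Chromophore absorption basis spectra, 500-1200 nm (synthetic/approximate).
# Landmark reconstruction of the standard compilations of hemoglobin, water
# and fat absorption; linearly interpolated onto a 1 nm grid at load time.
# mu_hbo2 / mu_hb are EFFECTIVE in-tissue hemoglobin absorption coefficients:
# whole-blood absorption (150 g Hb / L) pre-multiplied by a nominal 2% blood
# volume fraction, because the absorption mixing model carries no explicit
# blood-fraction multiplier.  Units: cm^-1.
wavelength_nm,mu_hbo2,mu_hb,mu_water,mu_fat
500,2.240,2.150,0.00025,0.0120
530,4.180,4.290,0.00032,0.0110
542,5.700,4.800,0.00036,0.0105
550,4.610,5.200,0.00045,0.0100
560,3.490,5.470,0.00050,0.0097
576,5.950,4.290,0.00070,0.0090
590,1.500,2.600,0.00120,0.0082
600,0.343,1.575,0.00220,0.0075
610,0.161,1.010,0.00250,0.0070
630,0.0654,0.552,0.00290,0.0063
650,0.0394,0.402,0.00320,0.0060
680,0.0300,0.260,0.00450,0.0060
700,0.0311,0.192,0.00600,0.0060
750,0.0555,0.1506,0.02620,0.0070
760,0.0620,0.1790,0.02560,0.0072
800,0.0874,0.0817,0.02000,0.0080
850,0.1134,0.0742,0.04330,0.0100
900,0.1284,0.0778,0.06790,0.0300
930,0.1300,0.0760,0.13500,0.1000
960,0.1290,0.0740,0.28000,0.0450
975,0.1280,0.0735,0.48500,0.0380
1000,0.1179,0.0675,0.36300,0.0300
1050,0.1050,0.0620,0.13000,0.0260
1100,0.0964,0.0568,0.17000,0.0700
1150,0.0850,0.0520,0.55000,0.3000
1200,0.0750,0.0482,1.04000,0.6000
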