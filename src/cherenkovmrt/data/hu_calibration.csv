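# Generic piecewise-linear CT scanner calibration (HU -> mass density g/cm3).
# Shipped as a fixture; real studies use the site-specific scanner curve.
hu,density
-1000,0.00121
-500,0.50
-100,0.95
0,1.00
55,1.05
300,1.25
1000,1.60
2000,2.20
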