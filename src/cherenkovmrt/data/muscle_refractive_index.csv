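# Muscle refractive index dispersion table (synthetic/approximate).
wavelength_nm,n
500,1.3950
600,1.3880
700,1.3820
800,1.3800
900,1.3790
1000,1.3785
1100,1.3778
1200,1.3774
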