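# Thyroid-tissue optical properties (synthetic/approximate literature
# substitute; the clinical study's exact source table is not printed).
# mu_a and the reduced scattering mu_s_prime in cm^-1; anisotropy g = 0.9 and
# refractive index n = 1.40 are applied separately.
wavelength_nm,mu_a,mu_s_prime
500,2.50,12.0
550,5.50,11.0
600,1.20,10.0
650,0.55,9.2
700,0.40,8.6
750,0.38,8.0
800,0.35,7.5
850,0.37,7.1
900,0.45,6.7
950,0.70,6.4
1000,0.60,6.1
1100,0.50,5.6
1200,0.90,5.2
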