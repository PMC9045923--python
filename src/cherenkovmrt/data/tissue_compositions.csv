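# Per-tissue chromophore compositions and Rayleigh/Mie scattering parameters
# (synthetic/approximate transcriptions of the standard tissue-optics
# compilations; structural placeholders where the exact clinical values are
# not published).
# so2: oxygen saturation; w/f/m: water, fat, melanin fractional components.
# a_cm: reduced scattering (cm^-1) at the 500 nm reference wavelength;
# f_ray: Rayleigh fraction; b_mie: Mie scatter power; g: anisotropy.
material,so2,w,f,m,a_cm,f_ray,b_mie,g
skin,0.60,0.65,0.00,0.0010,48.9,0.409,0.702,0.85
adipose,0.70,0.15,0.80,0.0000,18.4,0.174,0.447,0.90
muscle,0.70,0.75,0.03,0.0000,13.0,0.235,0.919,0.93
bone,0.80,0.25,0.30,0.0000,22.9,0.174,0.716,0.92
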