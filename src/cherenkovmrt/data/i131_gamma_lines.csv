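# Compact I-131 gamma line table: photon energy (MeV) and emission
# probability per decay.  Lines are emitted independently per decay.
energy_mev,intensity
0.284,0.0612
0.364,0.8150
0.637,0.0717
0.723,0.0177
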