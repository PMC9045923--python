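# Compact I-131 beta- branch table: endpoint kinetic energy (MeV) and branch
# intensity per decay (normalised at load).  Allowed-shape Fermi spectrum is
# assumed for every branch (daughter Z = 54).
endpoint_mev,intensity
0.247,0.0213
0.334,0.0723
0.606,0.8960
0.807,0.0040
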