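element	monoisotopic_mass
H	1.00782503207
C	12.0
C13	13.0033548378
N	14.0030740048
O	15.9949146196
P	30.97376163
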