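element,mass_number,monoisotopic_mass
H,1,1.00782503207
C,12,12.0
N,14,14.0030740048
O,16,15.9949146196
F,19,18.9984032200
Na,23,22.9897692809
P,31,30.9737616320
S,32,31.9720710015
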