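>SYNP0001.1 PPAR_SYNTHETIC
A [ 17  1  1  1  1 17 17 17  1  1  1  1 17 ]
C [  1  1  1  1 17  1  1  1  1  1  1 17  1 ]
G [  1 17 17  1  1  1  1  1 17 17  1  1  1 ]
T [  1  1  1 17  1  1  1  1  1  1 17  1  1 ]
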