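>SYNC0001.1 CEBP_SYNTHETIC
A [ 17  1  1  1  1  1  1 17 17  1 ]
C [  1  1  1  1 17  1 17  1  1  1 ]
G [  1  1  1 17  1 17  1  1  1  1 ]
T [  1 17 17  1  1  1  1  1  1 17 ]
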