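>NFKBLIKE
A [  1  1  1  1 37  1  1  1  1  1  1 37 ]
C [  1  1  1  1  1 37  1  1  1 37 37  1 ]
G [  1 37 37 37  1  1  1  1  1  1  1  1 ]
T [ 37  1  1  1  1  1 37 37 37  1  1  1 ]
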