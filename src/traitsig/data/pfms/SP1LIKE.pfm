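>SP1LIKE
A [ 37  1  1  1  1  1  1  1  1  1  1  1 ]
C [  1  1  1  1  1 37  1  1  1  1 37  1 ]
G [  1 37 37 37 37  1 37 37 37 37  1  1 ]
T [  1  1  1  1  1  1  1  1  1  1  1 37 ]
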