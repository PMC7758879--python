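MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.32 C 0.18 G 0.18 T 0.32

MOTIF UPRE_like_pwm
letter-probability matrix: alength= 4 w= 7 nsites= 25 E= 0
 0.04 0.04 0.88 0.04
 0.88 0.04 0.04 0.04
 0.04 0.88 0.04 0.04
 0.04 0.04 0.88 0.04
 0.04 0.04 0.04 0.88
 0.04 0.04 0.88 0.04
 0.45 0.05 0.05 0.45
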