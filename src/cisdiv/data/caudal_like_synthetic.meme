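MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF caudal_like_synthetic
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
 0.050 0.050 0.050 0.850
 0.050 0.050 0.050 0.850
 0.100 0.050 0.050 0.800
 0.850 0.050 0.050 0.050
 0.050 0.050 0.050 0.850
 0.050 0.100 0.700 0.150
 0.700 0.100 0.150 0.050
 0.700 0.100 0.100 0.100
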