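# Illustrative UPRE-style consensus motifs for demonstration and testing.
# These are NOT published binding-site definitions: the XBP-1s elements
# (ACGT core, CCACG box, UPRE A, UPRE B) are named in the literature but
# their matrices are external configuration; supply your own definitions
# for real analyses.
ACGT_core	ACGT
CCACG_box	CCACG
UPREA_like	GATGACGTGK
UPREB_like	ATTGCA
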