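"""Small built-in sequences used by examples and worked analyses."""

#: The 102 nucleotides appended directly downstream of the annotated AGO1
#: stop codon in the AGO1x expression construct (FLAG/HA-AGO1x).  Scanning
#: codons from its first base reaches a TAG after 99 nt; the 33-codon
#: stop-free prefix encodes the AGO1x C-terminal extension.
AGO1X_APPENDED_NT = (
    "aggcagaacgctgttacctcactggatagaagaaagctttccaagccccaggagctgtgccaccca"
    "aatccagaggaagcaaggaggagggaggtggggtag"
).upper()

#: Tryptic peptides of the AGO1x extension observed by targeted mass
#: spectrometry; both are substrings of the translated 33-aa extension.
AGO1X_TRYPTIC_PEPTIDES = ("QNAVTSLDR", "LSKPQELCHPNPEEAR")
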