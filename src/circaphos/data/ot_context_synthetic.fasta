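>Ot13g02360 synthetic 30-residue context window; the embedded SLGLLPGPTK peptide is real, the flanks are invented
MARDEVKTGASLGLLPGPTKVDESTARKLV
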