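# source=main-text RE probes and consensus-permutation series
# note=ConA/ConD/ConH are reconstructions from the described edit path (ConE -> +RY steps -> WW AT->TT), not verbatim printed sequences
name	sequence	spacer	provenance
GGGCA_full	GGGCATGCCCGGGCATGCCC	0	synthetic
GAACA_full	GAACATGTTCGAACATGTTC	0	synthetic
GGGCA_half	TGGGCATGCCCA	0	synthetic
GAACA_half	CGAACATGTTCG	0	synthetic
ConE	GAGCATGTCCGAGCATGTCC	0	synthetic
ConP	GGGCATGTCCGAGCATGTCC	0	synthetic
ConA_reconstruction	GGGCATGTCCGGGCATGTCC	0	synthetic
ConD_reconstruction	GGGCATGCCCGGGCATGCCC	0	synthetic
ConH_reconstruction	GGGCTTGCCCGGGCTTGCCC	0	synthetic
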