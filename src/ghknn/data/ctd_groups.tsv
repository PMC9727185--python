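property	group1	group2	group3
polarity	LIFWCMVY	PATGS	HQRKNED
hydrophobicity	RKEDQN	GASTPHY	CLVIMFW
normalized_vdw_volume	GASTPDC	NVEQIL	MHKFRYW
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
secondary_structure	EALMQKRH	VIYCWFT	GNPSD
solvent_accessibility	ALFCGIVW	RKQEND	MSPTHY
surface_tension	GQDNAHR	KTSEC	ILMFPWYV
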