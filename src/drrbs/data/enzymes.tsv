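# Default enzyme panel: methylation-insensitive restriction endonucleases
# columns: name <TAB> site-with-caret <TAB> [overhang override]
# The caret marks the top-strand cut; the 5' overhang (fill-in length) is
# derived as len(site) - 2*offset unless the third column overrides it.
# 3'-overhang cutters (HpyCH4III, BanII, SphI, KpnI) are approximated by
# blunt/minimal-overhang cuts inside the site: fragment boundaries shift by
# <=2 bp relative to the true chemistry, and no 3' extension is modelled
# (those bases are removed, not filled, during end repair).
MspI	C^CGG
ApeKI	G^CWGC
TaqaI	T^CGA
BssSI	C^ACGAG
HpyCH4V	TG^CA
AluI	AG^CT
BstNI	CC^WGG
HaeIII	GG^CC
HpyCH4III	AC^NGT
BanII	GRG^CYC
BglII	A^GATCT
SphI	GCA^TGC
BamHI	G^GATCC
KpnI	GGT^ACC
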