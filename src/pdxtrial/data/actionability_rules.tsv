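source	gene	alteration_class	variant	tier
genomic	PIK3CA	hotspot-mutation	H1047R	clinical
genomic	PIK3CA	hotspot-mutation	E545K	clinical
genomic	ERBB2	hotspot-mutation	L755S	clinical
genomic	FGFR1	amplification		preclinical
genomic	MYC	amplification		preclinical
genomic	MDM2	amplification		preclinical
genomic	ATM	truncating		preclinical
genomic	ARID1A	truncating		preclinical
genomic	CDH1	truncating		preclinical
genomic	PIK3R1	truncating		preclinical
genomic	PTEN	deletion		preclinical
genomic	INPP4B	deletion		preclinical
expression	AR	outlier-high		clinical
expression	CD274	outlier-high		clinical
expression	ESR1	outlier-high		clinical
expression	ERBB2	outlier-high		clinical
protein	AR	outlier-high		clinical
protein	CD274	outlier-high		clinical
protein	pHER2	outlier-high		clinical
protein	AKT	outlier-high		preclinical
protein	pChk1	outlier-high		preclinical
protein	pChk2	outlier-high		preclinical
protein	FASN	outlier-high		preclinical
protein	FAK	outlier-high		preclinical
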