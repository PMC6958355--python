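enzyme	kind	p4	p3	p2	p1	p1p	p2p	p3p	p4p
Pa	pattern	*	*	*	FL	*	*	*	*
Pa	pattern	*	*	*	*	FL	*	*	*
Pb	pattern	*	*	*	FLWY	*	*	*	*
Pb	pattern	*	*	*	*	FLWY	*	*	*
T	pattern	*	*	*	KR	^P	*	*	*
T	pattern	*	*	W	K	P	*	*	*
T	pattern	*	*	M	R	P	*	*	*
T	exception	*	*	CD	K	D	*	*	*
T	exception	*	*	C	K	HY	*	*	*
T	exception	*	*	C	R	K	*	*	*
T	exception	*	*	R	R	HR	*	*	*
CT_high	pattern	*	*	*	FY	^P	*	*	*
CT_high	pattern	*	*	*	W	^MP	*	*	*
CT_low	pattern	*	*	*	FLY	^P	*	*	*
CT_low	pattern	*	*	*	W	^MP	*	*	*
CT_low	pattern	*	*	*	M	^PY	*	*	*
CT_low	pattern	*	*	*	H	^DMPW	*	*	*
E	pattern	DE	DE	DE	K	*	*	*	*
Th	pattern	*	*	G	R	G	*	*	*
Th	pattern	AFGILTVM	AFGILTVW	P	R	^DE	^DE	*	*
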