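pqr	r187	r196
pQR2595	D	S
pQR2596	E	P
pQR2597	Y	T
pQR2598	D	G
pQR2599	Y	T
pQR2600	D	G
pQR2601	D	S
pQR2602	D	A
pQR2603	N	A
pQR2604	D	G
pQR2605	Y	T
pQR2606	N	A
pQR2607	Y	G
pQR2608	D	G
pQR2609	D	T
pQR2610	E	P
pQR2611	D	G
pQR2612	D	T
pQR2613	Y	T
pQR2614	N	A
pQR2615	D	T
pQR2616	E	P
pQR2617	Y	T
pQR2618	D	G
pQR2619	N	A
pQR2620	D	T
pQR2621	D	T
pQR2622	E	P
pQR2623	Y	T
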