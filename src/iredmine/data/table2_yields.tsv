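enzyme	substrate	product	mode	yield_uncoupled	yield_coupled	ee	major_isomer
pQR2595	3a	3b	product_formation	33	74	>99	R
pQR2595	4a	4b	substrate_consumption	44	90	ND	ND
pQR2600	1a	1b	product_formation	21	84	93	R
pQR2600	4a	4b	substrate_consumption	74	92	ND	ND
pQR2601	1a	1b	product_formation	23	98	>99	R
pQR2601	4a	4b	substrate_consumption	21	91	ND	ND
pQR2612	5a	5b	product_formation	23	76	>99	S
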