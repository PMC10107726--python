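cofactor_binding	GLGxMGx5[ATS]x4Gx4[VIL]WNR[TS]x2[KR]
active_site	Gx[DE]x[GDA]x[APS]x3{K}x[ASL]x[LMVIAG]
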