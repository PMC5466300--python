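id	protein	well	construct	species	yield_ug_ml
D02_Clone01	ZmRGP1	a4	Δ135–361	Zea mays	30.3
D04_Clone01	FvMUCI10	a6	Δ1–91	Fragaria vesca	35.9
D18_Clone03	CsGlcAT14A	a9	Δ1–29 and Δ343–396	Cucumis sativus	86.3
D02_Clone02	ZmRGP1	b4	Δ237–361	Zea mays	23.5
D08_Clone01	SiDUF246	b5	Δ1–63	Setaria italic	24.3
D13_Clone03	GmIRX14	b7	Δ1–78 and Δ436–502	Glycine max	119.8
D04_Clone03	FvMUCI10	c6	Δ1–91 and Δ393–457	Fragaria vesca	120.6
D22_Clone01	FvDUF288	c7	Δ1–95	Fragaria vesca	110.8
D03_Clone01	SlXXT1	c9	Δ1–46	Solanum lycopersicum	40.2
D04_Clone04	FvMUCI10	d6	Δ1–57 and Δ393–457	Fragaria vesca	223.5
D22_Clone03	FvDUF288	e7	Δ1–95 and Δ311–761	Fragaria vesca	45.9
D06_Clone02	GmGALS1	e8	Δ1–49	Glycine max	21.3
D21_Clone01	SlDUF288	e9	Δ1–104	Solanum lycopersicum	56.2
D13_Clone04	GmIRX14	f5	Δ1–156 and Δ436–502	Glycine max	94.8
D23_Clone01	VvRRA	g5	Δ1–53	Vitis vinifera	63.3
D20_Clone01	GmEMB2756	g6	Δ1–104	Glycine max	20.0
D24_Clone01	GmXEG113	h6	Δ1–52	Glycine max	41.2
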