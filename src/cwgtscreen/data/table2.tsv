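protein	construct	vector	chaperones	yield_ug_ml
At1g53290	Δ1–50	pET55dest	DnaK, DnaJ, GrpE	5.3
At1g53290	full-length	pET55dest	DnaK, DnaJ, GrpE	18.0
At1g53290	Δ1–50	pET32dest	DnaK, DnaJ, GrpE	1.2
At1g53290	full-length	pET32dest	Trigger Factor	0.4
FUT6	Δ1–12 and Δ507–519	pET22dest	Trigger Factor	1.8
Galt31A	full-length	pET32dest	Trigger Factor	0.6
GUT1/IRX10L	Δ1–46	pET55dest	DnaK, DnaJ, GrpE	0.6
GUT1/IRX10L	Δ1–46	pET32dest	Trigger Factor	1.0
IRX9	full-length	pET32dest	DnaK, DnaJ, GrpE	4.6
IRX9	full-length	pET32dest	Trigger Factor	0.8
IRX9	Δ1–72	pET55dest	Trigger Factor	7.0
MUR3	Δ1–100	pET55dest	DnaK, DnaJ, GrpE	6.8
PARVUS	Δ1–39	pET55dest	Trigger Factor	1.6
RGP1	full-length	pET55dest	none	111.0
RGP1	full-length	pET55dest	GroEL, GroES	271.8
RGP1	full-length	pET32dest	Trigger Factor	1.3
RGP1	full-length	pET32dest	DnaK, DnaJ, GrpE	1.6
XXT1	full-length	pET32dest	Trigger Factor	9.6
XXT1	full-length	pET32dest	DnaK, DnaJ, GrpE	10.9
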