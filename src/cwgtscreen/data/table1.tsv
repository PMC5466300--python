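protein	gene_identifier	family	organism
ARAD1	At2g35100	GT47	Arabidopsis thaliana (thale cress)
ARAD2	At5g44930	GT47	Arabidopsis thaliana (thale cress)
EMB2756	100797815	DUF616	Glycine max (soy bean)
FUT6	At1g14080	GT37	Arabidopsis thaliana (thale cress)
GALS1	At2g33570	GT92	Arabidopsis thaliana (thale cress)
GALS1	100787815	GT92	Glycine max (soy bean)
Galt31A	At1g32930	GT31	Arabidopsis thaliana (thale cress)
GAUT1	At3g61130	GT8	Arabidopsis thaliana (thale cress)
GAUT7	At2g38650	GT8	Arabidopsis thaliana (thale cress)
GlcAT14A	101210575	GT14	Cucumis sativus (cucumber)
GUT1/IRX10L	At5g61840	GT47	Arabidopsis thaliana (thale cress)
GUT1/IRX10L	100783737	GT47	Glycine max (soy bean)
GUT1/IRX10L	100794632	GT47	Glycine max (soy bean)
GUX1	At3g18660	GT8	Arabidopsis thaliana (thale cress)
IRX7	At2g28110	GT47	Arabidopsis thaliana (thale cress)
IRX8	At5g54690	GT8	Arabidopsis thaliana (thale cress)
IRX9	At2g37090	GT43	Arabidopsis thaliana (thale cress)
IRX9L	At1g27600	GT43	Arabidopsis thaliana (thale cress)
IRX9L	606306	GT43	Hordeum vulgare (barley)
IRX14	At4g36890	GT43	Arabidopsis thaliana (thale cress)
IRX14	100777505	GT43	Glycine max (soy bean)
MGD2	At3g48820	GT29	Arabidopsis thaliana (thale cress)
MUCI10	101291758	GT34	Fragaria vesca (strawberry)
MUCI10	4350696	GT34	Oryza sativa (rice)
MUR3	At2g20370	GT47	Arabidopsis thaliana (thale cress)
NN	At1g53290	GT31	Arabidopsis thaliana (thale cress)
DUF246	101299994	DUF246	Fragaria vesca (strawberry)
DUF246	101311123	DUF246	Fragaria vesca (strawberry)
DUF246	101776477	DUF246	Setaria italic (foxtail millet)
PARVUS	At1g19300	GT8	Arabidopsis thaliana (thale cress)
PARVUS	101228909	GT8	Cucumis sativus (cucumber)
PARVUS	4336486	GT8	Oryza sativa (rice)
RGP1	At3g02230	GT75	Arabidopsis thaliana (thale cress)
RGP1	100282614	GT75	Zea mays (corn)
RGP1	100836426	GT75	Brachypodion distachyon (stiff brome)
RGXT2	At4g01750	GT77	Arabidopsis thaliana (thale cress)
RRA	100255856	GT77	Vitis vinifera (grape)
RRA2	At1g75110	GT77	Arabidopsis thaliana (thale cress)
DUF288	101253530	DUF288	Solanum lycopersicum
DUF288	101309981	DUF288	Fragaria vesca (strawberry)
DUF288	101510562	DUF288	Cicer arietinum (chickpea)
TBL13	100802467	DUF231	Glycine Max (soy bean)
TBL29	100825801	DUF231	Brachypodion distachyon (stiff brome)
XEG113	100819032	GT77	Glycine max (soy bean)
XXT1	At3g62720	GT34	Arabidopsis thaliana (thale cress)
XXT1	101262652	GT34	Solanum lycopersicum (tomato)
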