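# Monoisotopic element masses (Da), IUPAC/CODATA values.
# element	monoisotopic_mass
H	1.00782503207
C	12.0
N	14.0030740048
O	15.9949146196
S	31.97207100
P	30.97376163
Se	78.9718499
Na	22.9897692809
K	38.96370668
Li	7.01600455
Ca	39.96259098
Mg	23.9850417
Fe	55.9349375
Zn	63.9291422
Cu	62.9295975
Cl	34.96885268
Br	78.9183371
F	18.99840322
I	126.904473
Si	27.9769265325
B	11.0093054
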