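# Bundled Unimod name -> monoisotopic mass (Da) subset.
# name	monoisotopic_mass
Acetyl	42.010565
Amidated	-0.984016
Ammonia-loss	-17.026549
Biotin	226.077598
Carbamidomethyl	57.021464
Carbamyl	43.005814
Carboxymethyl	58.005479
Cation:K	37.955882
Cation:Na	21.981943
Deamidated	0.984016
Dehydrated	-18.010565
Dimethyl	28.031300
Dioxidation	31.989829
Formyl	27.994915
Gln->pyro-Glu	-17.026549
Glu->pyro-Glu	-18.010565
GlyGly	114.042927
Guanidinyl	42.021798
Hex	162.052824
HexNAc	203.079373
iTRAQ4plex	144.102063
iTRAQ8plex	304.205360
Label:13C(6)	6.020129
Label:13C(6)15N(2)	8.014199
Label:13C(6)15N(4)	10.008269
Label:18O(2)	4.008491
Malonyl	86.000394
Methyl	14.015650
Methylthio	45.987721
Myristoyl	210.198366
Nethylmaleimide	125.047679
Nitro	44.985078
Oxidation	15.994915
Palmitoyl	238.229666
Phospho	79.966331
Propionamide	71.037114
Propionyl	56.026215
Pyridylethyl	105.057849
Succinyl	100.016044
Sulfo	79.956815
TMT2plex	225.155833
TMT6plex	229.162932
TMTpro	304.207146
Trimethyl	42.046950
Trioxidation	47.984744
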