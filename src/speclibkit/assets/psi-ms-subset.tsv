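# Bundled PSI-MS controlled-vocabulary subset (snapshot; swap in a current
# psi-ms.obo extract for production use).
# accession	name	value_kind
MS:1000041	charge state	number
MS:1000045	collision energy	number
MS:1000129	negative scan	none
MS:1000130	positive scan	none
MS:1000465	scan polarity	term
MS:1000744	selected ion m/z	number
MS:1000888	stripped peptide sequence	string
MS:1001456	analysis software	string
MS:1002350	PSM-level global FDR	number
MS:1003053	theoretical monoisotopic m/z	number
MS:1003057	scan number	number
MS:1003059	number of spectra	number
MS:1003061	library spectrum name	string
MS:1003063	universal spectrum identifier	string
MS:1003065	spectrum aggregation type	term
MS:1003066	singleton spectrum	none
MS:1003067	consensus spectrum	none
MS:1003069	number of replicate spectra available	number
MS:1003070	number of replicate spectra used	number
MS:1003072	spectrum origin type	term
MS:1003169	proforma peptidoform sequence	string
MS:1003186	library format version	string
MS:1003188	library name	string
MS:1003203	constituent spectrum file	string
MS:1003208	experimental precursor monoisotopic m/z	number
MS:1003212	library attribute set name	string
MS:1003254	peak attribute	term
MS:1003267	cluster member spectrum keys	string
MS:1003275	other attribute name	string
MS:1003276	other attribute value	string
MS:1003279	observation frequency of peak	none
UO:0000266	electronvolt	none
UO:0000221	dalton	none
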