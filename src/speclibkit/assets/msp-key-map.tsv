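# Legacy MSP key -> CV term mapping.
# msp_key	accession	name	context	transform
# transform: identity | number | polarity | aggregation | nreps | charge
PrecursorMZ	MS:1000744	selected ion m/z	spectrum	number
PrecursorMz	MS:1000744	selected ion m/z	spectrum	number
Precursor	MS:1000744	selected ion m/z	spectrum	number
Parent	MS:1000744	selected ion m/z	spectrum	number
PEPMASS	MS:1000744	selected ion m/z	spectrum	number
ObservedPrecursorMZ	MS:1000744	selected ion m/z	spectrum	number
SelectedIonMZ	MS:1000744	selected ion m/z	spectrum	number
Q1	MS:1000744	selected ion m/z	spectrum	number
Polarity	MS:1000465	scan polarity	spectrum	polarity
Ion_mode	MS:1000465	scan polarity	spectrum	polarity
IonMode	MS:1000465	scan polarity	spectrum	polarity
ION_MODE	MS:1000465	scan polarity	spectrum	polarity
Ionization_mode	MS:1000465	scan polarity	spectrum	polarity
Scan_polarity	MS:1000465	scan polarity	spectrum	polarity
CE	MS:1000045	collision energy	spectrum	number
HCD	MS:1000045	collision energy	spectrum	number
CID	MS:1000045	collision energy	spectrum	number
Collision_energy	MS:1000045	collision energy	spectrum	number
CollisionEnergy	MS:1000045	collision energy	spectrum	number
COLLISION_ENERGY	MS:1000045	collision energy	spectrum	number
CollisionEnergy(eV)	MS:1000045	collision energy	spectrum	number
Energy	MS:1000045	collision energy	spectrum	number
Charge	MS:1000041	charge state	analyte	charge
Spec	MS:1003065	spectrum aggregation type	spectrum	aggregation
Nreps	MS:1003070	number of replicate spectra used	spectrum	nreps
Scan	MS:1003057	scan number	spectrum	number
USI	MS:1003063	universal spectrum identifier	spectrum	identity
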