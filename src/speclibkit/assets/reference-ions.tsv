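# Named reference ions (isobaric-reporter ions and friends).
# m/z is the singly charged ion m/z; formula left blank where the species
# carries isotope labels our formula grammar does not encode.
# name	formula	mz
TMT126		126.127726
TMT127N		127.124761
TMT127C		127.131081
TMT128N		128.128116
TMT128C		128.134436
TMT129N		129.131471
TMT129C		129.137790
TMT130N		130.134825
TMT130C		130.141145
TMT131		131.138180
TMT131C		131.144499
TMT132N		132.141535
TMT132C		132.147855
TMT133N		133.144890
TMT133C		133.151210
TMT134N		134.148245
TMT135N		135.151600
iTRAQ113		113.107325
iTRAQ114		114.110680
iTRAQ115		115.107715
iTRAQ116		116.111069
iTRAQ117		117.114424
iTRAQ118		118.111459
iTRAQ119		119.114813
iTRAQ121		121.121523
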