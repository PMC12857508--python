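taxonomy_code,specialty_code
208D00000X,01
207Q00000X,08
207R00000X,11
207RG0300X,38
207RC0000X,06
2084N0400X,13
207RG0100X,20
207RP1001X,29
207RR0500X,66
207RH0003X,83
207RX0202X,90
363L00000X,50
364S00000X,89
363A00000X,97
111N00000X,35
152W00000X,41
225100000X,65
193200000X,70
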