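##TITLE=2,3-Pentanedione
##JCAMP-DX=4.24
##DATA TYPE=MASS SPECTRUM
##MW=100
##NPOINTS=7
##PEAK TABLE=(XY..XY)
15,14
27,25
29,60
42,12
43,100
57,32
100,11
##END=
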