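# -10 promoter hexamers (sigma70-type consensus TATAAT family); synthetic
# default training set bundled with the package, one site per line.
TATAAT
TATAAT
TATACT
TATGAT
TACAAT
TAAAAT
TGTAAT
CATAAT
TATAGT
TATTAT
TATAAA
GATAAT
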