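# -35 promoter hexamers (sigma70-type consensus TTGACA family); synthetic
# default training set bundled with the package, one site per line.
TTGACA
TTGACA
TTGACT
TTGACG
TTGATA
TTGCCA
TTTACA
TGGACA
CTGACA
TTGAAA
TTGTCA
ATGACA
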