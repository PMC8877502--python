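# N. crassa proteins more abundant in the VDAC-less (ΔPor-1) strain that are also
# predicted from transcript levels to be upregulated under ER unfolded-protein-response
# induction (DTT or tunicamycin). One NCU accession per line.
NCU05780
NCU09519
NCU10572
NCU01272
NCU02549
NCU09559
NCU09560
NCU05770
NCU03739
NCU04930
NCU01589
NCU09674
NCU03611
NCU03795
NCU03949
NCU05881
NCU10810
NCU02727
NCU06738
NCU01166
NCU03596
NCU06974
NCU00864
NCU09223
NCU10360
NCU05495
NCU01004
NCU00685
NCU00350
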