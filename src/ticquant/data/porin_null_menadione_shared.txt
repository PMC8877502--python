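# N. crassa proteins more abundant in the VDAC-less (ΔPor-1) strain that are also
# more abundant in menadione-treated (oxidatively stressed) cells.
# One NCU accession per line.
NCU05780
NCU09559
NCU05770
NCU04930
NCU00355
NCU09674
NCU02812
NCU08402
NCU02727
NCU08004
NCU06974
NCU00685
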