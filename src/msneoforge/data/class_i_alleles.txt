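# Default MHC Class I allele panel (27 high-frequency alleles)
HLA-A*01:01
HLA-A*02:01
HLA-A*02:03
HLA-A*02:06
HLA-A*03:01
HLA-A*11:01
HLA-A*23:01
HLA-A*24:02
HLA-A*26:01
HLA-A*30:01
HLA-A*30:02
HLA-A*31:01
HLA-A*32:01
HLA-A*33:01
HLA-A*68:01
HLA-A*68:02
HLA-B*07:02
HLA-B*08:01
HLA-B*15:01
HLA-B*35:01
HLA-B*40:01
HLA-B*44:02
HLA-B*44:03
HLA-B*51:01
HLA-B*53:01
HLA-B*57:01
HLA-B*58:01
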