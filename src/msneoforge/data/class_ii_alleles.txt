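# Default MHC Class II allele panel (27 high-frequency alleles;
# DQ/DP entries are alpha/beta chain pairs joined by "-")
DRB1*01:01
DRB1*03:01
DRB1*04:01
DRB1*04:05
DRB1*07:01
DRB1*08:02
DRB1*09:01
DRB1*11:01
DRB1*12:01
DRB1*13:02
DRB1*15:01
DRB3*01:01
DRB3*02:02
DRB4*01:01
DRB5*01:01
DQA1*05:01-DQB1*02:01
DQA1*05:01-DQB1*03:01
DQA1*03:01-DQB1*03:02
DQA1*04:01-DQB1*04:02
DQA1*01:01-DQB1*05:01
DQA1*01:02-DQB1*06:02
DPA1*02:01-DPB1*01:01
DPA1*01:03-DPB1*02:01
DPA1*01:03-DPB1*04:01
DPA1*03:01-DPB1*04:02
DPA1*02:01-DPB1*05:01
DPA1*02:01-DPB1*14:01
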