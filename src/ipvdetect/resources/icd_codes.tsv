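# IPV-related diagnosis codes, two columns: code <TAB> revision.
# 995.83 covers both adult sexual abuse and adult rape; stored once
# (matching is set membership).
995.83	9
995.82	9
995.81	9
995.8	9
E967.0	9
E967.9	9
994.7	9
T76.21XA	10
T76.51XA	10
T76.11XA	10
T74.11XA	10
T74.21XA	10
T74.51XA	10
T71.9XXA	10
T71.163A	10
T71.193A	10
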