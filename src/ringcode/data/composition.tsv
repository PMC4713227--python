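sensilla	expected_count
at1	20
at2	20
at3	30
at4	60
ab1	55
ab2	30
ab3	30
ab4	20
ab5	15
ab6	10
ab7	15
ab8	10
ab9	10
ab10	15
ac1	20
ac2	20
ac3	20
ac4	15
ai1	10
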