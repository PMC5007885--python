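# Per-clade consensus domain series, member counts, clade-specific blocks and
# the N-terminal glycine/arginine repeat block, for the four plant AGO clades.
# "series" lists the clade's consensus domain series in N-to-C order;
# "specific_blocks" are blocks found in >=1 member of this clade and no other;
# repeat_block "-" means the clade carries no N-terminal repeat.
clade	n_members	series	specific_blocks	repeat_block
AGO2/3/7	44	A-4;DUF1785-2;PAZ-3;B-4;PIWI-3	45,48	43
AGO4/6/8/9	55	A-2;DUF1785-2;PAZ-2;B-2;PIWI-1	28,30,32,37,42,46,50	-
AGO5	28	A-3;DUF1785-3;PAZ-3;B-3;PIWI-2	-	43
AGO1/10	58	A-1;DUF1785-1;PAZ-1;B-1;PIWI-1	-	43
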