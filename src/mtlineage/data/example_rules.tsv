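# Example motif rule table (control-region motifs).
# M7c1 and F1a4a1 rules are the CR variant patterns of the two most frequent
# haplotypes in the reference dataset; P/P1 use the minimal HVS pattern
# [73G 263G 315.1C] 16357C.  Forbidden column: '.' = none.
Haplogroup	Parent	Required	Forbidden	MinFrame
M7c1	.	73G 146C 199C 263G 16223T 16295T 16362C	.	16024-16569;1-576
F1a4a1	.	73G 152C 249del 263G 16129A 16172C 16294T 16304C 16362C	.	16024-16569;1-576
P	.	73G 263G 16357C	.	16024-16569;1-576
P1	P	73G 263G 315.1C 16357C	.	16024-16569;1-576
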