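# Example background amino-acid composition: database-average residue
# frequencies of the UniProtKB/Swiss-Prot protein knowledgebase (release
# statistics), renormalized over the 20 standard residues.  Supply your own
# file of 20 "letter probability" pairs to override.
A 0.0826
C 0.0138
D 0.0546
E 0.0672
F 0.0387
G 0.0707
H 0.0228
I 0.0591
K 0.0580
L 0.0968
M 0.0241
N 0.0406
P 0.0474
Q 0.0394
R 0.0553
S 0.0665
T 0.0536
V 0.0686
W 0.0110
Y 0.0292
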