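# Coarse synthetic mini-phylotree for haplogroup calling.
# Marker sets are expressed relative to the packaged reference (an
# H-lineage baseline), so the tree is rooted at H. Topology follows the
# human mtDNA phylogeny at 2-3 level resolution: K derives from U8b
# (via U8/U), J and T share the JT node, I/W/X sit under an N node,
# V under HV. Resolution and marker content are deliberately coarse.
# columns: name, parent ('-' for root), comma-separated defining variants
H	-
HV	H	m.16311T>C
V	HV	m.72T>C,m.4580G>A
JT	H	m.73A>G,m.4216T>C,m.11251A>G
J	JT	m.295C>T,m.13708G>A,m.16069C>T
T	JT	m.709G>A,m.16294C>T
U	H	m.73A>G,m.11467A>G,m.12308A>G,m.12372G>A
U8	U	m.1811A>G
U8b	U8	m.3480A>G,m.9055G>A,m.14167C>T
K	U8b	m.11299T>C,m.14798T>C,m.16224T>C
N	H	m.73A>G,m.8701A>G,m.10398A>G
I	N	m.10034T>C,m.16129G>A
W	N	m.204T>C,m.1243T>C
X	N	m.153A>G,m.6221T>C
B	H	m.73A>G,m.16189T>C,m.16217T>C
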