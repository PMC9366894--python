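# Per-residue amino-acid frequencies for the two-state prion-like-domain HMM.
# prion: composition of experimentally verified yeast prion-forming domains
#   (Alberti et al. 2009, as adopted by the PLAAC scoring scheme of
#   Lancaster et al. 2014); transcribed best-effort from the published
#   parameterisation and renormalised to sum to 1.
# human_background: amino-acid composition of the reviewed human proteome
#   (UniProtKB/Swiss-Prot release statistics), renormalised to sum to 1.
aa	prion	human_background
A	0.0449	0.0701
C	0.0020	0.0230
D	0.0219	0.0473
E	0.0219	0.0710
F	0.0259	0.0365
G	0.1017	0.0657
H	0.0130	0.0263
I	0.0199	0.0433
K	0.0329	0.0573
L	0.0369	0.0996
M	0.0160	0.0213
N	0.1875	0.0359
P	0.0499	0.0631
Q	0.2164	0.0477
R	0.0249	0.0564
S	0.0958	0.0833
T	0.0459	0.0536
V	0.0190	0.0597
W	0.0010	0.0122
Y	0.0229	0.0267
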