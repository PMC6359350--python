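mutation	expected_label	ddssv	source
H228T	beneficial	-186.18	Bgl1B glucose tolerance
V174C/A404V/L441F	beneficial	-246.22	optimal temperature / pH shift
H184F	beneficial	100.37	glucose inhibition constant
P172L	beneficial	-6.29	catalytic efficiency
P172L/F250A	beneficial	-6.29	catalytic efficiency
L167W	beneficial	-602.80	optimal temperature and glucose tolerance
L167W/P172L	beneficial	-615.46	activity increase (2x)
L167W/P172L/P338F	beneficial	-615.46	activity increase (1.3x)
V168Y	not_beneficial	330.56	reduced specific activity
F225S	not_beneficial	-365.07	reduced specific activity
Y308F	not_beneficial	34.19	reduced specific activity
Y308A	not_beneficial	-108.62	reduced specific activity
I207V	beneficial	-71.56	increased specificity constant
N218H	beneficial	-230.61	Km decrease (~2-fold)
N273V	not_beneficial	-55.26	Km increase (~5-fold)
F252I	not_beneficial	86.70	reduced substrate affinity
F252W	not_beneficial	129.97	reduced substrate affinity
F252Y	not_beneficial	37.86	reduced substrate affinity
M284N	not_beneficial	-127.35	kcat/Km reduction (7-30x)
H276M	not_beneficial	-501.32	kcat/Km reduction (2-6x)
V173C	not_beneficial	13.59	decreased cellobiose affinity
M177L	not_beneficial	20.86	decreased cellobiose affinity (small)
D229N	not_beneficial	18.11	decreased cellobiose affinity (high)
H231D	not_beneficial	-54.22	decreased cellobiose affinity
E96K	beneficial	-31.08	improved thermostability
N223G	not_beneficial	39.37	reduced transglycosylation / tolerance / activity
N223Q	not_beneficial	264.34	reduced transglycosylation / tolerance / activity
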