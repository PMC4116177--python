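# Backbone-independent side-chain rotamer set: canonical chi combinations
# (gauche-/trans/gauche+ staggered minima; aromatic chi2 at the two ring
# orientations).  Angles in degrees.  Empty field = residue has fewer chis.
# residue	chi1	chi2	chi3
PHE	-65	90
PHE	-65	-85
PHE	180	90
PHE	180	-85
PHE	62	90
PHE	62	-85
TYR	-65	90
TYR	-65	-85
TYR	180	90
TYR	180	-85
TYR	62	90
TYR	62	-85
ILE	-65	168
ILE	-65	-60
ILE	-65	60
ILE	180	168
ILE	180	-60
ILE	180	60
ILE	62	168
ILE	62	-60
ILE	62	60
LEU	-65	175
LEU	-65	65
LEU	-65	-60
LEU	180	175
LEU	180	65
LEU	180	-60
LEU	62	175
LEU	62	65
LEU	62	-60
MET	-65	-65	-75
MET	-65	-65	180
MET	-65	-65	75
MET	-65	180	-75
MET	-65	180	180
MET	-65	180	75
MET	-65	65	-75
MET	-65	65	180
MET	-65	65	75
MET	180	-65	-75
MET	180	-65	180
MET	180	-65	75
MET	180	180	-75
MET	180	180	180
MET	180	180	75
MET	180	65	-75
MET	180	65	180
MET	180	65	75
MET	62	-65	-75
MET	62	-65	180
MET	62	-65	75
MET	62	180	-75
MET	62	180	180
MET	62	180	75
MET	62	65	-75
MET	62	65	180
MET	62	65	75
VAL	175
VAL	-60
VAL	60
ALA
GLY
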