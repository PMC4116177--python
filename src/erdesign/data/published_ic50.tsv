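# Reported IC50 ± SE from the four-replicate competitive fluorescence-
# polarization binding assay: wild-type human ERα ligand-binding domain and
# the M421F / M421I point mutants against six ligands.  Experimental inputs
# for fold-change analysis; not recomputable from this package.
receptor	ligand	ic50	se	unit
wt	17beta-estradiol	16	4	nM
wt	17alpha-ethinylestradiol	12	6	nM
wt	bisphenol-A	11	2.5	uM
wt	tamoxifen	47	14	nM
wt	4-nonylphenol	8	1	uM
wt	4-tert-octylphenol	11.4	1.5	uM
M421F	17beta-estradiol	7	2	nM
M421F	17alpha-ethinylestradiol	2.1	0.9	nM
M421F	bisphenol-A	1.9	0.5	uM
M421F	tamoxifen	55	40	nM
M421F	4-nonylphenol	4	2	uM
M421F	4-tert-octylphenol	10	4	uM
M421I	17beta-estradiol	191	50	nM
M421I	17alpha-ethinylestradiol	90	21	nM
M421I	bisphenol-A	100	9	uM
M421I	tamoxifen	830	300	nM
M421I	4-nonylphenol	60	30	uM
M421I	4-tert-octylphenol	200	60	uM
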