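# Human ERα ligand-binding-domain complexes used to reproduce the published
# 25-residue union pocket at a 6 Å cutoff.  The coordinate files are NOT
# shipped with the package: fetch them with
#
#     python scripts/fetch_structures.py examples/real_structures
#
# Author numbering in these entries already follows human ERα numbering, so
# no reference sequence is needed for the mapping.
structures:
  - path: 1ERE.pdb    # ERα LBD with 17β-estradiol
    id: 1ERE
    ligand: EST
    chain: A
  - path: 3ERT.pdb    # ERα LBD with 4-hydroxytamoxifen
    id: 3ERT
    ligand: OHT
    chain: A
  - path: 3UU7.pdb    # ERα LBD with a bisphenol-class EDC
    id: 3UU7
    chain: A          # ligand auto-selected (largest non-water hetero group)
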