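"""Profile pocket conservation and enumerate natural-variant mutations.

Builds a 200-sequence ortholog alignment whose column at reference
position 421 carries the composition seen across ER orthologs — mostly M,
with I/L and a notable F minority — and asks which substitutions nature
already licenses there.
"""

from erdesign import candidate_mutations, column_profile
from erdesign.synthetic_data import make_alignment

alignment = make_alignment(
    n_sequences=200,
    column_specs={421: {"M": 170, "L": 5, "I": 3, "F": 22}},
    seed=7,
    reference_overrides={421: "M"},  # the reference (human-like) row keeps M
)

profile = column_profile(alignment, 421)
print(f"position 421: modal residue {profile.modal_residue}, "
      f"conservation {profile.conservation:.2f} over {profile.n_effective} sequences")
print(f"counts: {profile.counts}")

for cand in candidate_mutations([profile], min_support=2):
    print(f"  candidate {cand}: seen in {cand.support} species "
          f"({100 * cand.variant_fraction:.1f}%)")
# Candidates are ranked by how often the variant occurs; the aromatic
# M421F substitution leads because 22 orthologs already carry F there.
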