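"""Design an immunized repair donor and its single-guide cassette.

Picks a random locus/edit/guide combination, builds the 50+50 bp donor
carrying the codon change, and shows the substitutions the designer
applied — payload edits realize the amino-acid change, immunizing edits
are synonymous marks that stop the nuclease from re-cutting the repaired
allele.
"""

from hicas12a import assemble_cassette, builtin_profile, check_recleavage, design_donor
from hicas12a.pam import default_dr
from hicas12a.synth import random_design_case

profile = builtin_profile("impLbCas12a")
locus, edit, guide = random_design_case(seed=1)

wt_codon = locus.codon(edit.codon_index)
print(f"edit: codon {edit.codon_index} {wt_codon} -> {edit.target}")
print(f"guide: {guide.strand} strand, PAM {guide.pam_seq}, cut at {guide.cleavage_pos + 1}")

donor = design_donor(locus, edit, guide, profile)
print(f"donor: {len(donor.upstream_arm)} bp arm | {len(donor.edited_core)} bp core | "
      f"{len(donor.downstream_arm)} bp arm")
for sub in donor.edits_applied:
    print(f"  {sub.pos + 1}: {sub.ref}>{sub.alt} ({sub.purpose})")
print("re-cleavable after repair:", check_recleavage(donor.apply_to(locus), guide, profile))

cassette = assemble_cassette([(guide.spacer, donor)], dr=default_dr())
print("cassette parts:", " - ".join(name for name, _ in cassette.parts))
print(f"cassette length: {len(cassette.sequence)} bp")
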