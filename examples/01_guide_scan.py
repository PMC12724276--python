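"""Scan a locus for Cas12a guide sites and rank them for an intended edit.

Builds a synthetic 1-kb ORF, scans both strands for 4-nt PAMs recognized
by impLbCas12a (the most PAM-relaxed variant in the registry), and ranks
the candidates for a codon substitution at position 150.
"""

from hicas12a import CodonEdit, builtin_profile, rank_guides, scan_guides
from hicas12a.pam import guides_report
from hicas12a.synth import random_locus

locus = random_locus(seed=1, length=999)
profile = builtin_profile("impLbCas12a")

sites = scan_guides(locus, profile, min_class="high")
ranked = rank_guides(sites, CodonEdit(150, "A"), locus)

print(f"{len(sites)} high-class guide sites on {locus.id} ({len(locus)} bp)")
print(guides_report(ranked).head(5).to_string(index=False))
print(
    "\nColumns are 1-based. cleavage_pos is the nominal cut, 18 bp beyond the\n"
    "PAM; edit_distance_bp is the signed distance from that cut to the codon\n"
    "being edited - guides within +-20 bp (the high window) rank first."
)
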