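"""Plan a two-step PAM-replacement test for a low-efficiency PAM.

A palindromic TATA PAM gives two overlapping guide sites, one per
strand. Step 1 uses the opposite-strand guide to install a test PAM
(here TGTC) in place of the TATA and to plant a TAA stop codon as a
phenotypic marker. Step 2 uses the original efficient guide — now
reading the installed test PAM — to revert the strain to the wild-type
protein; the reversion rate measures the test PAM's activity.
"""

from hicas12a import builtin_profile, design_pam_replacement, scan_guides, translate
from hicas12a.synth import palindromic_pam_locus

profile = builtin_profile("impLbCas12a")
locus, pam_pos = palindromic_pam_locus(seed=7)
guide = next(
    g for g in scan_guides(locus, profile, min_class="high")
    if g.pam_sense_start == pam_pos and g.strand == "+"
)

for test_pam in ("TGTC", "TTTT", "TCTG"):
    plan = design_pam_replacement(guide, test_pam, locus, profile)
    installed = plan.step1_locus.seq[pam_pos : pam_pos + 4]
    final = plan.step2_donor.apply_to(plan.step1_locus)
    print(
        f"{guide.pam_seq} -> {test_pam}: installed={installed} "
        f"step1_edits={len(plan.step1_donor.edits_applied)} "
        f"step2_reverts_protein={translate(final, 0) == locus.protein()} "
        f"test_pam_class={plan.step2_guide.efficiency_class}"
    )
print(
    "\nEach line is one planned experiment: the installed 4-mer, how many base\n"
    "changes step 1 writes, and whether step 2's donor restores the wild-type\n"
    "protein (it always must)."
)
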