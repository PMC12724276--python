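"""Enumerate an NNK saturation library over five consecutive codons.

NNK (N = any base, K = G/T) encodes all 20 amino acids plus one stop in
32 codons, so a 5-codon scan is 160 distinct constructs spanning a 15 bp
edited region — small enough to keep inside the high editing window of a
single guide.
"""

from hicas12a import coverage_fold, nnk_scan
from hicas12a.synth import random_design_case

locus, edit, guide = random_design_case(seed=0)
lo = edit.codon_index - 2
lib = nnk_scan(locus, (lo, lo + 4), guide)

print(f"target codons {lib.target_codons[0]}..{lib.target_codons[1]} "
      f"({lib.region_bp} bp edited region)")
print(f"distinct constructs: {lib.distinct_constructs}")
print(f"amino-acid classes per position: {lib.to_frame().encoded_aa.nunique()}")
print(f"coverage at 1.6e4 transformants: {coverage_fold(16_000, lib.distinct_constructs):g}-fold")
print("\nfirst degenerate primer pair (NNK + downstream anchor / upstream anchor rc):")
ci, fwd, rev = lib.primers[0]
print(f"  codon {ci}: fwd={fwd}  rev={rev}")
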