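"""Synthetic loci and design cases for testing and demonstrations.

The real target genes (ADE2, PfDHFR, Sc-optDHFR) are not distributed
with the package; these generators build random loci with the same
geometric properties — an ORF, recognizable PAM sites, room for 50 bp
homology arms — so every design and analysis stage can be exercised
reproducibly from a seed.
"""

from __future__ import annotations

import numpy as np

from .pam import GuideSite, PamProfile, builtin_profile, scan_guides, window_class
from .seqcore import CODON_TO_AA, CodonEdit, LocusSequence, translate

__all__ = ["random_locus", "random_design_case", "palindromic_pam_locus"]

_BASES = np.array(list("ACGT"))


def random_locus(
    seed: int, length: int = 999, locus_id: str | None = None, frame_start: int = 0
) -> LocusSequence:
    """Uniform-random locus whose whole sense strand is treated as the ORF."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(_BASES, size=length))
    return LocusSequence(locus_id or f"synlocus_{seed}", seq, frame_start)


def random_design_case(
    seed: int,
    profile: PamProfile | None = None,
    length: int = 999,
    margin: int = 70,
    max_edit_distance: int = 18,
) -> tuple[LocusSequence, CodonEdit, GuideSite]:
    """A random locus plus a compatible (edit, guide) pair for donor design.

    The guide has a high-class PAM, its cleavage site sits away from the
    locus ends so 50 bp arms always fit, and the edited codon lies within
    the high editing window of the cut.
    """
    profile = profile or builtin_profile("impLbCas12a")
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        locus = random_locus(int(rng.integers(2**31)), length)
        sites = [
            g
            for g in scan_guides(locus, profile, min_class="high")
            if margin <= g.cleavage_pos < len(locus) - margin
        ]
        if not sites:
            continue
        guide = sites[int(rng.integers(len(sites)))]
        codon_idxs = [
            ci
            for ci in range(1, locus.n_codons + 1)
            for (s, e) in [locus.codon_interval(ci)]
            if margin <= s and e <= len(locus) - margin
            and max(abs(s - guide.cleavage_pos), abs(e - 1 - guide.cleavage_pos))
            <= max_edit_distance
        ]
        if not codon_idxs:
            continue
        ci = codon_idxs[int(rng.integers(len(codon_idxs)))]
        wt_aa = CODON_TO_AA[locus.codon(ci)]
        choices = [a for a in "ACDEFGHIKLMNPQRSTVWY*" if a != wt_aa]
        target = choices[int(rng.integers(len(choices)))]
        return locus, CodonEdit(ci, target), guide
    raise RuntimeError(f"no design case found for seed {seed}")


def palindromic_pam_locus(
    seed: int, length: int = 600, pam_pos: int = 300, pam: str = "TATA"
) -> tuple[LocusSequence, int]:
    """Random ORF locus with a palindromic PAM planted at ``pam_pos``.

    A palindromic 4-mer (reverse complement of itself, e.g. TATA) creates
    two guide sites at the same PAM, one per strand — the geometry used
    to install replacement PAMs with an opposite-strand guide. Returns
    the locus and the sense-strand PAM start.
    """
    locus = random_locus(seed, length, locus_id=f"palpam_{seed}")
    seq = locus.seq[:pam_pos] + pam + locus.seq[pam_pos + len(pam) :]
    return locus.with_seq(seq), pam_pos
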