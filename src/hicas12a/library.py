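"""NNK saturation-scanning library design and coverage arithmetic.

An NNK codon (N = any base, K = G/T) spans 32 codons encoding all 20
amino acids plus a single stop (TAG), halving the codon space relative
to NNN while keeping full residue coverage. Scanning k consecutive
codons therefore yields 32*k distinct plasmid constructs — 160 for the
five-codon scan used to saturate a short catalytic region.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import pandas as pd

from .pam import GuideSite, window_class
from .seqcore import CODON_TO_AA, LocusSequence, SequenceError, revcomp

__all__ = [
    "NNK_CODONS",
    "NNKLibrary",
    "nnk_scan",
    "coverage_fold",
    "AACoverage",
    "aa_coverage",
]

#: The 32 codons of the NNK degenerate scheme, lexicographic.
NNK_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", "ACGT", "GT")
)


@dataclass(frozen=True)
class NNKLibrary:
    """One NNK construct family per codon of a contiguous target range."""

    locus_id: str
    target_codons: tuple[int, int]  # 1-based inclusive
    constructs: tuple[tuple[int, str], ...]  # (codon_index, concrete codon)
    primers: tuple[tuple[int, str, str], ...]  # (codon_index, fwd, rev)

    @property
    def n_positions(self) -> int:
        lo, hi = self.target_codons
        return hi - lo + 1

    @property
    def distinct_constructs(self) -> int:
        return len(set(self.constructs))

    @property
    def region_bp(self) -> int:
        return 3 * self.n_positions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"codon_index": ci, "codon": c, "encoded_aa": CODON_TO_AA[c]}
                for ci, c in self.constructs
            ]
        )

    def primers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"codon_index": ci, "fwd_primer": f, "rev_primer": r}
                for ci, f, r in self.primers
            ]
        )


def nnk_scan(
    locus: LocusSequence,
    codon_range: tuple[int, int],
    guide: GuideSite,
    anchor: int = 20,
) -> NNKLibrary:
    """Design an NNK scan across a contiguous 1-based codon range.

    Emits one degenerate inverse-PCR primer pair per position (mutagenic
    forward primer = NNK plus a downstream anchor; reverse primer anneals
    immediately upstream). Warns when any edited base falls outside the
    high editing window of the supplied guide, since incorporation drops
    with distance from the cut.
    """
    lo, hi = codon_range
    if lo < 1 or hi < lo or hi > locus.n_codons:
        raise SequenceError(f"codon range {codon_range} outside ORF (1..{locus.n_codons})")
    s0, _ = locus.codon_interval(lo)
    _, e1 = locus.codon_interval(hi)
    worst = max(abs(s0 - guide.cleavage_pos), abs(e1 - 1 - guide.cleavage_pos))
    if window_class(worst) != "high":
        warnings.warn(
            f"edited region extends {worst} bp from the cleavage site, beyond the "
            "high editing window",
            stacklevel=2,
        )
    constructs = tuple(
        (ci, codon) for ci in range(lo, hi + 1) for codon in NNK_CODONS
    )
    primers = []
    for ci in range(lo, hi + 1):
        s, e = locus.codon_interval(ci)
        fwd = "NNK" + locus.seq[e : e + anchor]
        rev = revcomp(locus.seq[max(0, s - anchor) : s])
        primers.append((ci, fwd, rev))
    return NNKLibrary(locus.id, (lo, hi), constructs, tuple(primers))


def coverage_fold(transformants: int, library_size: int) -> float:
    """Transformants per distinct construct (e.g. 1.6e4 / 160 = 100-fold)."""
    if library_size <= 0:
        raise SequenceError("library_size must be positive")
    if transformants < 0:
        raise SequenceError("transformants must be non-negative")
    return transformants / library_size


@dataclass(frozen=True)
class AACoverage:
    """Observed fraction of possible amino-acid substitutions, with the
    numerator and denominator exposed so other counting conventions can
    be recomputed by the caller."""

    fraction: float
    numerator: int
    denominator: int


def aa_coverage(
    observed_variants: set[tuple[int, str]],
    codon_range: tuple[int, int],
    wildtype_protein: str,
) -> AACoverage:
    """Fraction of possible substitutions observed across the range.

    The default convention counts 20 non-wild-type outcomes per position
    (the 19 other residues plus stop as one class); wild-type-synonymous
    observations do not count toward the numerator.
    """
    lo, hi = codon_range
    if hi < lo or lo < 1 or hi > len(wildtype_protein):
        raise SequenceError(f"codon range {codon_range} outside protein of length {len(wildtype_protein)}")
    for pos, _ in observed_variants:
        if not lo <= pos <= hi:
            raise SequenceError(f"observed position {pos} outside range {codon_range}")
    letters = set("ACDEFGHIKLMNPQRSTVWY*")
    numerator = len(
        {
            (pos, aa)
            for pos, aa in observed_variants
            if aa in letters and aa != wildtype_protein[pos - 1]
        }
    )
    denominator = 20 * (hi - lo + 1)
    return AACoverage(numerator / denominator, numerator, denominator)
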