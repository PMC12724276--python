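"""Homology donor construction, crRNA/donor cassette assembly, Golden Gate
oligo emission, and the two-step PAM-replacement experiment design.

The homology-integrated layout places the repair donor directly 3' of the
crRNA spacer, so one plasmid unit carries guide and donor together:

    TEF1p - pre-tRNA(Gly) - DR - spacer - donor - CYC1t

with additional DR-spacer-donor blocks (optionally preceded by the AAAT
synSeparator) for multiplex arrays. A donor is two 50 bp homology arms
flanking an edited core; after applying the payload codon change the
design is re-scanned, and if the guide could still cleave the edited
sequence a synonymous "immunizing" mutation is added — preferably inside
the PAM, otherwise in the protospacer as close to the cut as possible,
since edits incorporate best near the cleavage site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .pam import (
    CLEAVAGE_OFFSET,
    EFFICIENCY_ORDER,
    PAM_LEN,
    WINDOW_HIGH,
    WINDOW_LOW,
    GuideSite,
    PamProfile,
    scan_guides,
    window_class,
)
from .seqcore import (
    CODON_TO_AA,
    CodonEdit,
    LocusSequence,
    SequenceError,
    codons_for,
    revcomp,
    translate,
)

__all__ = [
    "Substitution",
    "DonorDesign",
    "DesignError",
    "check_recleavage",
    "design_donor",
    "donor_from_substitutions",
    "CassetteDesign",
    "assemble_cassette",
    "DEFAULT_PARTS",
    "SYN_SEPARATOR",
    "GoldenGateOligos",
    "Excision",
    "goldengate_oligos",
    "simulate_excision",
    "PamReplacementPlan",
    "design_pam_replacement",
    "cassette_to_genbank",
    "donor_to_genbank",
]

ARM_LENGTH = 50
SYN_SEPARATOR = "AAAT"

# Synthetic stand-in part sequences (fixed, arbitrary DNA of realistic
# length; the pre-tRNA is 77 bp to match the cassette architecture).
# Real constructs should override these via RunConfig.parts.
DEFAULT_PARTS: dict[str, str] = {
    "TEF1p": (
        "GAAGGAGGTAGCTTGATCTGTTGTCCTGGGCTGTCTTTCGGGCTTGCTGAGGGATCTGGAGG"
        "AGGAGATTGTCGCTGCCTAGGCGAGAGAGGGAGGCTCGAATGCGCGGATCAAAAGCGG"
    ),
    "pre_tRNA_Gly": (
        "CCGCTCCGCATAGTCAAATAACCCGAGCGCGTGCACACTATGCGTAGCTTGTGCTTCAGTGGACTTTCGGAGAAACT"
    ),
    "CYC1t": (
        "GAAGTGATGCACGTAGGATTGAGCAAGAGCACCTTTAAGAAAGAGAGAGGGCTGAAACCTACC"
        "GGACTCCCTGTATACTTCCGCTTTGAC"
    ),
}


class DesignError(SequenceError):
    """A donor or cassette design cannot be completed as requested."""


@dataclass(frozen=True)
class Substitution:
    """One base change on the sense strand (0-based position)."""

    pos: int
    ref: str
    alt: str
    purpose: str  # payload | immunizing


@dataclass(frozen=True)
class DonorDesign:
    """A repair donor: two homology arms around an edited core.

    Arms match the unedited locus exactly; ``core_start``/``core_end``
    are the 0-based half-open locus coordinates of the edited core.
    """

    upstream_arm: str
    edited_core: str
    downstream_arm: str
    edits_applied: tuple[Substitution, ...]
    core_start: int
    core_end: int
    recleavable: bool

    @property
    def sequence(self) -> str:
        return self.upstream_arm + self.edited_core + self.downstream_arm

    def apply_to(self, locus: LocusSequence) -> str:
        """Reconstruct the full edited locus sequence."""
        return locus.seq[: self.core_start] + self.edited_core + locus.seq[self.core_end :]


def _apply(seq: str, subs: Sequence[Substitution]) -> str:
    out = list(seq)
    for s in subs:
        if out[s.pos] != s.ref:
            raise DesignError(
                f"substitution ref mismatch at {s.pos}: expected {s.ref}, found {out[s.pos]}"
            )
        out[s.pos] = s.alt
    return "".join(out)


def check_recleavage(
    edited_locus: str,
    guide: GuideSite,
    profile: PamProfile,
    min_class: str = "low",
) -> bool:
    """Could the guide still cleave the edited sequence?

    Exact-match policy: true iff the guide's full spacer occurs perfectly,
    on either strand, immediately 3' of a PAM classifying >= ``min_class``.
    Any spacer mismatch or a class-none PAM counts as non-cleavable.
    """
    min_rank = EFFICIENCY_ORDER[min_class]
    for strand_seq in (edited_locus, revcomp(edited_locus)):
        start = 0
        while (i := strand_seq.find(guide.spacer, start)) >= 0:
            if i >= PAM_LEN:
                pam = strand_seq[i - PAM_LEN : i]
                if EFFICIENCY_ORDER[profile.classify(pam)] >= min_rank:
                    return True
            start = i + 1
    return False


def _choose_payload_codon(wt_codon: str, edit: CodonEdit, codon_pref: dict | None) -> str:
    if edit.is_codon:
        return edit.target
    candidates = codons_for(edit.target)
    best_d = min(sum(a != b for a, b in zip(wt_codon, c)) for c in candidates)
    tied = sorted(c for c in candidates if sum(a != b for a, b in zip(wt_codon, c)) == best_d)
    if codon_pref:
        tied.sort(key=lambda c: (-codon_pref.get(c, 0.0), c))
    return tied[0]


def _orf_interval(locus: LocusSequence) -> tuple[int, int]:
    return locus.frame_start, locus.frame_start + 3 * locus.n_codons


def _find_immunizing(
    locus: LocusSequence,
    edited: str,
    guide: GuideSite,
    profile: PamProfile,
    min_class: str,
) -> list[Substitution] | None:
    """One synonymous codon swap that abolishes re-cleavage.

    Candidate positions: the PAM first (most specific disruption), then
    protospacer positions by proximity to the cleavage site — distant
    synonymous marks co-convert poorly, so near-cut positions are safer.
    """
    pam_lo, pam_hi = guide.pam_sense_interval()
    proto_lo, proto_hi = guide.protospacer_sense_interval()
    candidates = list(range(pam_lo, pam_hi)) + sorted(
        range(proto_lo, proto_hi), key=lambda p: (abs(p - guide.cleavage_pos), p)
    )
    orf_lo, orf_hi = _orf_interval(locus)
    for strict in (True, False):
        for pos in candidates:
            if not orf_lo <= pos < orf_hi:
                continue
            off = (pos - orf_lo) % 3
            cstart = pos - off
            cur = edited[cstart : cstart + 3]
            syns = [
                c
                for c in codons_for(CODON_TO_AA[cur])
                if c != cur and (not strict or c[off] != cur[off])
            ]
            syns.sort(key=lambda c: (sum(a != b for a, b in zip(cur, c)), c))
            for c in syns:
                trial = edited[:cstart] + c + edited[cstart + 3 :]
                if not check_recleavage(trial, guide, profile, min_class):
                    return [
                        Substitution(cstart + k, cur[k], c[k], "immunizing")
                        for k in range(3)
                        if cur[k] != c[k]
                    ]
    return None


def donor_from_substitutions(
    locus: LocusSequence,
    subs: Sequence[Substitution],
    guide: GuideSite,
    profile: PamProfile,
    arm_length: int = ARM_LENGTH,
    min_class: str = "low",
    expected_protein: str | None = None,
) -> DonorDesign:
    """Build a donor applying explicit substitutions, then immunize.

    The edited sequence is re-scanned; while the guide could still cleave
    it, synonymous immunizing mutations are added (PAM positions first).
    Arms of ``arm_length`` bp flank the minimal interval covering every
    applied change.
    """
    if not subs:
        raise DesignError("no substitutions to apply")
    edited = _apply(locus.seq, subs)
    for _ in range(8):
        if not check_recleavage(edited, guide, profile, min_class):
            break
        imm = _find_immunizing(locus, edited, guide, profile, min_class)
        if imm is None:
            raise DesignError(
                "no synonymous immunizing mutation available in PAM or protospacer; "
                "supply an explicit immunizing edit"
            )
        edited = _apply(edited, imm)
    if check_recleavage(edited, guide, profile, min_class):
        raise DesignError("design still re-cleavable after immunization")
    if expected_protein is not None and translate(edited, locus.frame_start) != expected_protein:
        raise DesignError("edited ORF does not translate to the intended protein")

    payload_pos = {s.pos for s in subs if s.purpose == "payload"}
    diffs = [i for i, (a, b) in enumerate(zip(locus.seq, edited)) if a != b]
    applied = tuple(
        Substitution(
            i, locus.seq[i], edited[i], "payload" if i in payload_pos else "immunizing"
        )
        for i in diffs
    )
    cs, ce = min(diffs), max(diffs) + 1
    if cs < arm_length or ce + arm_length > len(locus):
        raise DesignError(
            f"edited interval [{cs}, {ce}) too close to the locus boundary "
            f"for {arm_length} bp homology arms"
        )
    return DonorDesign(
        upstream_arm=locus.seq[cs - arm_length : cs],
        edited_core=edited[cs:ce],
        downstream_arm=locus.seq[ce : ce + arm_length],
        edits_applied=applied,
        core_start=cs,
        core_end=ce,
        recleavable=False,
    )


def design_donor(
    locus: LocusSequence,
    edits: CodonEdit | Sequence[CodonEdit],
    guide: GuideSite,
    profile: PamProfile,
    arm_length: int = ARM_LENGTH,
    min_class: str = "low",
    codon_pref: dict | None = None,
) -> DonorDesign:
    """Design a repair donor installing one or more codon edits.

    The payload codon is the minimum-substitution codon for each target
    residue (ties broken by ``codon_pref`` weights, else lexicographic).
    If the payload leaves the guide site intact, a synonymous immunizing
    mutation is added and the design re-scanned until non-recleavable.

    Warns when an edit sits beyond the declining editing window of the
    guide's cleavage site; errors on identity edits.
    """
    if isinstance(edits, CodonEdit):
        edits = [edits]
    if not edits:
        raise DesignError("no edits given")
    intended = list(locus.protein())
    subs: list[Substitution] = []
    for edit in edits:
        s, e = locus.codon_interval(edit.codon_index)
        wt_codon = locus.codon(edit.codon_index)
        new_codon = _choose_payload_codon(wt_codon, edit, codon_pref)
        if new_codon == wt_codon:
            raise DesignError(
                f"identity edit: codon {edit.codon_index} is already {wt_codon} "
                f"({CODON_TO_AA[wt_codon]})"
            )
        intended[edit.codon_index - 1] = CODON_TO_AA[new_codon]
        d = max(abs(s - guide.cleavage_pos), abs(e - 1 - guide.cleavage_pos))
        if window_class(d) == "low":
            warnings.warn(
                f"codon {edit.codon_index} lies {d} bp from the cleavage site, "
                "beyond the declining editing window; expect poor incorporation",
                stacklevel=2,
            )
        subs.extend(
            Substitution(s + k, wt_codon[k], new_codon[k], "payload")
            for k in range(3)
            if wt_codon[k] != new_codon[k]
        )
    return donor_from_substitutions(
        locus,
        subs,
        guide,
        profile,
        arm_length=arm_length,
        min_class=min_class,
        expected_protein="".join(intended),
    )


# ---------------------------------------------------------------------------
# Cassette assembly


@dataclass(frozen=True)
class CassetteDesign:
    """An ordered crRNA(+donor) expression cassette, single or arrayed."""

    parts: tuple[tuple[str, str], ...]
    multiplex_order: tuple[str, ...]
    separator_used: bool

    @property
    def sequence(self) -> str:
        return "".join(seq for _, seq in self.parts)


def assemble_cassette(
    units: Sequence[tuple[str, DonorDesign | str]],
    dr: str,
    use_separator: bool = False,
    parts: dict[str, str] | None = None,
) -> CassetteDesign:
    """Concatenate TEF1p - pre-tRNA - (DR - spacer - donor)xk - CYC1t.

    ``units`` are (spacer, donor) pairs in the desired expression order;
    with ``use_separator`` the AAAT synSeparator precedes each DR after
    the first. Unit order is preserved as given.
    """
    if not units:
        raise DesignError("cassette needs at least one (spacer, donor) unit")
    registry = {**DEFAULT_PARTS, **(parts or {})}
    out: list[tuple[str, str]] = [
        ("TEF1p", registry["TEF1p"]),
        ("pre_tRNA_Gly", registry["pre_tRNA_Gly"]),
    ]
    spacers = []
    for i, (spacer, donor) in enumerate(units, start=1):
        donor_seq = donor.sequence if isinstance(donor, DonorDesign) else donor
        if use_separator and i > 1:
            out.append(("synSeparator", SYN_SEPARATOR))
        out.append(("DR", dr))
        out.append((f"spacer_{i}", spacer))
        out.append((f"donor_{i}", donor_seq))
        spacers.append(spacer)
    out.append(("CYC1t", registry["CYC1t"]))
    return CassetteDesign(tuple(out), tuple(spacers), use_separator)


# ---------------------------------------------------------------------------
# Golden Gate


@dataclass(frozen=True)
class GoldenGateOligos:
    """Amplification oligos carrying Type IIS sites and fusion overhangs."""

    forward: str
    reverse: str
    amplicon: str
    enzyme_site: str
    overhangs: tuple[str, str]
    internal_sites: tuple[tuple[int, str], ...]  # (1-based pos, strand) — empty on success


@dataclass(frozen=True)
class Excision:
    """Fragment released by simulated Type IIS digestion (top strand)."""

    top_strand: str
    left_overhang: str
    right_overhang: str
    overhang_len: int

    @property
    def insert(self) -> str:
        return self.top_strand[self.overhang_len :]


def _site_positions(seq: str, site: str) -> list[tuple[int, str]]:
    hits = []
    for strand, pattern in (("+", site), ("-", revcomp(site))):
        start = 0
        while (i := seq.find(pattern, start)) >= 0:
            hits.append((i + 1, strand))
            start = i + 1
    return sorted(hits)


def goldengate_oligos(
    insert: str,
    enzyme_site: str = "GGTCTC",
    overhangs: tuple[str, str] = ("AATG", "GCTT"),
    anchor: int = 20,
) -> GoldenGateOligos:
    """Emit a primer pair that flanks ``insert`` with Type IIS sites.

    The default enzyme is BsaI-style (cuts 1 nt downstream, 4-nt 5'
    overhangs). The insert must be free of internal recognition sites on
    both strands — internal hits are reported with 1-based positions and
    raise, since the user must recode them.
    """
    oh1, oh2 = overhangs
    if oh1 == oh2:
        raise DesignError("identical fusion overhangs would ligate ambiguously")
    if len(oh1) != 4 or len(oh2) != 4:
        raise DesignError("fusion overhangs must be 4-mers")
    internal = _site_positions(insert, enzyme_site)
    if internal:
        raise DesignError(
            f"insert contains internal {enzyme_site} site(s) at "
            + ", ".join(f"{p}({s})" for p, s in internal)
        )
    if len(insert) < anchor:
        anchor = len(insert)
    fwd = enzyme_site + "A" + oh1 + insert[:anchor]
    rev = enzyme_site + "A" + revcomp(oh2) + revcomp(insert)[:anchor]
    amplicon = enzyme_site + "A" + oh1 + insert + oh2 + "T" + revcomp(enzyme_site)
    return GoldenGateOligos(fwd, rev, amplicon, enzyme_site, (oh1, oh2), ())


def simulate_excision(
    amplicon: str,
    enzyme_site: str = "GGTCTC",
    cut_offset: int = 1,
    overhang_len: int = 4,
) -> Excision:
    """Simulated digestion of a dsDNA amplicon (given as its top strand).

    Returns the released fragment; for oligos emitted by
    :func:`goldengate_oligos`, ``excision.insert`` reproduces the input
    insert byte-for-byte.
    """
    i = amplicon.find(enzyme_site)
    j = amplicon.rfind(revcomp(enzyme_site))
    if i < 0 or j < 0 or j <= i:
        raise DesignError("amplicon lacks a convergent pair of recognition sites")
    a = i + len(enzyme_site) + cut_offset
    b = j - cut_offset - overhang_len
    top = amplicon[a:b]
    return Excision(
        top_strand=top,
        left_overhang=top[:overhang_len],
        right_overhang=amplicon[b : b + overhang_len],
        overhang_len=overhang_len,
    )


# ---------------------------------------------------------------------------
# Two-step PAM replacement (install test PAM + stop, then revert)


@dataclass(frozen=True)
class PamReplacementPlan:
    """Two-step test of a candidate PAM at a validated efficient guide.

    Step 1: an opposite-strand installer guide writes the test PAM in
    place of the efficient guide's PAM and plants a TAA stop codon
    nearby (outside the efficient guide's protospacer), producing a
    phenotypically marked strain. Step 2: the efficient guide, now
    reading the installed test PAM, reverts the strain to the wild-type
    protein sequence; the reversion rate reports the test PAM's activity.
    """

    test_pam: str
    installer_guide: GuideSite
    step1_donor: DonorDesign
    step1_locus: LocusSequence
    step2_guide: GuideSite
    step2_donor: DonorDesign
    notes: tuple[str, ...]


def _replace(site: GuideSite, **kw) -> GuideSite:
    from dataclasses import replace as _r

    return _r(site, **kw)


def design_pam_replacement(
    high_eff_guide: GuideSite,
    test_pam: str,
    locus: LocusSequence,
    profile: PamProfile,
    arm_length: int = ARM_LENGTH,
    min_class: str = "low",
) -> PamReplacementPlan:
    """Plan the two-step replacement experiment for ``test_pam``.

    Requires an opposite-strand guide (recognizable PAM) whose editing
    window covers every base of the efficient guide's PAM; installers
    with all PAM bases inside the high window are preferred, the
    declining window is accepted.
    """
    if len(test_pam) != PAM_LEN:
        raise DesignError(f"test PAM must be {PAM_LEN} nt")
    notes: list[str] = [
        "minimal step-1 design: only the PAM replacement and the stop codon are "
        "programmed; immunizing changes are added automatically if required"
    ]
    if test_pam == high_eff_guide.pam_seq:
        warnings.warn("test PAM equals the original PAM: null experiment", stacklevel=2)
        notes.append("null experiment: test PAM equals original PAM")

    pam_lo, pam_hi = high_eff_guide.pam_sense_interval()
    proto_lo, proto_hi = high_eff_guide.protospacer_sense_interval()
    other = "-" if high_eff_guide.strand == "+" else "+"

    def max_pam_dist(g: GuideSite) -> int:
        return max(abs(p - g.cleavage_pos) for p in range(pam_lo, pam_hi))

    candidates = [
        g
        for g in scan_guides(locus, profile, min_class="high")
        if g.strand == other and max_pam_dist(g) <= WINDOW_LOW
    ]
    if not candidates:
        raise DesignError(
            "no opposite-strand guide whose editing window covers the PAM to replace"
        )
    installer = min(candidates, key=lambda g: (max_pam_dist(g), g.pam_sense_start))

    # step-1 substitutions: write the test PAM (as read on the efficient
    # guide's strand) onto the sense strand, plus a TAA stop codon.
    sense_new = test_pam if high_eff_guide.strand == "+" else revcomp(test_pam)
    subs = [
        Substitution(pam_lo + k, locus.seq[pam_lo + k], sense_new[k], "payload")
        for k in range(PAM_LEN)
        if locus.seq[pam_lo + k] != sense_new[k]
    ]
    orf_lo, orf_hi = _orf_interval(locus)
    blocked = set(range(pam_lo, pam_hi)) | set(range(proto_lo, proto_hi))
    stop_candidates = []
    for cstart in range(orf_lo, orf_hi - 2, 3):
        codon_span = set(range(cstart, cstart + 3))
        if codon_span & blocked:
            continue
        if locus.seq[cstart : cstart + 3] == "TAA":
            continue
        d = max(abs(cstart - installer.cleavage_pos), abs(cstart + 2 - installer.cleavage_pos))
        if d <= WINDOW_HIGH:
            stop_candidates.append((d, cstart))
    if not stop_candidates:
        raise DesignError(
            "no codon for the TAA stop within the installer's high editing window"
        )
    _, cstart = min(stop_candidates)
    wt_codon = locus.seq[cstart : cstart + 3]
    subs.extend(
        Substitution(cstart + k, wt_codon[k], "TAA"[k], "payload")
        for k in range(3)
        if wt_codon[k] != "TAA"[k]
    )

    step1_donor = donor_from_substitutions(
        locus, subs, installer, profile, arm_length=arm_length, min_class=min_class
    )
    step1_locus = locus.with_seq(step1_donor.apply_to(locus))

    # step-2: the efficient guide now reads the installed test PAM;
    # revert every protein-changing codon back to wild type.
    step2_guide = _replace(
        high_eff_guide,
        pam_seq=test_pam,
        efficiency_class=profile.classify(test_pam),
    )
    wt_protein = locus.protein()
    revert: list[Substitution] = []
    for cstart in range(orf_lo, orf_hi - 2, 3):
        cur = step1_locus.seq[cstart : cstart + 3]
        orig = locus.seq[cstart : cstart + 3]
        if cur != orig and CODON_TO_AA[cur] != CODON_TO_AA[orig]:
            revert.extend(
                Substitution(cstart + k, cur[k], orig[k], "payload")
                for k in range(3)
                if cur[k] != orig[k]
            )
    if not revert:
        raise DesignError("step-1 design changed no amino acid; nothing to revert")
    step2_donor = donor_from_substitutions(
        step1_locus,
        revert,
        step2_guide,
        profile,
        arm_length=arm_length,
        min_class=min_class,
        expected_protein=wt_protein,
    )
    return PamReplacementPlan(
        test_pam=test_pam,
        installer_guide=installer,
        step1_donor=step1_donor,
        step1_locus=step1_locus,
        step2_guide=step2_guide,
        step2_donor=step2_donor,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# GenBank emission


def _record(seq: str, name: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=name[:16], name=name[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "linear"
    rec.annotations["date"] = "01-JAN-2000"  # fixed for reproducible output
    return rec


def cassette_to_genbank(cassette: CassetteDesign, name: str = "cassette") -> SeqRecord:
    """Annotated GenBank record with one feature per cassette part."""
    rec = _record(cassette.sequence, name)
    pos = 0
    for part_name, seq in cassette.parts:
        rec.features.append(
            SeqFeature(
                FeatureLocation(pos, pos + len(seq)),
                type="misc_feature",
                qualifiers={"label": [part_name]},
            )
        )
        pos += len(seq)
    return rec


def donor_to_genbank(donor: DonorDesign, name: str = "donor") -> SeqRecord:
    rec = _record(donor.sequence, name)
    n_up = len(donor.upstream_arm)
    n_core = len(donor.edited_core)
    for label, lo, hi in (
        ("upstream_arm", 0, n_up),
        ("edited_core", n_up, n_up + n_core),
        ("downstream_arm", n_up + n_core, len(donor.sequence)),
    ):
        rec.features.append(
            SeqFeature(
                FeatureLocation(lo, hi), type="misc_feature", qualifiers={"label": [label]}
            )
        )
    for sub in donor.edits_applied:
        p = sub.pos - donor.core_start + n_up
        rec.features.append(
            SeqFeature(
                FeatureLocation(p, p + 1),
                type="variation",
                qualifiers={"label": [f"{sub.ref}>{sub.alt} ({sub.purpose})"]},
            )
        )
    return rec
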