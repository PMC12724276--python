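"""Sequence primitives shared by the design and analysis modules.

DNA here is always an uppercase string over {A, C, G, T}. Reference
sequences (loci, amplicons, donors) must be unambiguous; only *patterns*
— PAM codes such as ``TNTN`` or degenerate primers containing ``NNK`` —
may carry IUPAC ambiguity codes. Coordinates are 0-based half-open
internally; user-facing reports are 1-based inclusive.

Translation and codon logic use the standard nuclear genetic code
(the host is *S. cerevisiae* and the targets are codon-optimised ORFs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceError",
    "IUPAC_SETS",
    "DNA_ALPHABET",
    "revcomp",
    "iupac_match",
    "expand_iupac",
    "translate",
    "codons_for",
    "min_nt_substitutions",
    "at_content",
    "LocusSequence",
    "CodonEdit",
    "read_locus",
    "write_fasta",
]


class SequenceError(ValueError):
    """Invalid sequence, pattern, or coordinate."""


DNA_ALPHABET = frozenset("ACGT")

#: Degenerate nucleotide codes (IUPAC) mapped to their concrete base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# codon -> amino acid (stop as '*'), and the reverse grouping
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    CODONS_BY_AA.setdefault(CODON_TO_AA[_codon], ())
    CODONS_BY_AA[CODON_TO_AA[_codon]] += (_codon,)


def _check_dna(dna: str, what: str = "sequence") -> str:
    if not dna:
        raise SequenceError(f"empty {what}")
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid characters in {what}: {sorted(bad)}")
    return dna


def revcomp(dna: str) -> str:
    """Reverse complement of an unambiguous DNA string.

    An involution: ``revcomp(revcomp(x)) == x``.
    """
    _check_dna(dna)
    return dna.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every base of ``window`` lies in the degenerate set of the
    corresponding ``pattern`` position.

    ``pattern`` may contain IUPAC codes (e.g. ``"TTTV"``, ``"TNTN"``);
    ``window`` must be unambiguous DNA of the same length.
    """
    if len(pattern) != len(window):
        raise SequenceError(
            f"pattern/window length mismatch: {len(pattern)} vs {len(window)}"
        )
    _check_dna(window, "window")
    try:
        return all(w in IUPAC_SETS[p] for p, w in zip(pattern, window))
    except KeyError as exc:
        raise SequenceError(f"invalid IUPAC code {exc.args[0]!r} in pattern") from exc


def expand_iupac(pattern: str) -> Iterator[str]:
    """Enumerate every concrete DNA string matching a degenerate pattern."""
    try:
        sets = [sorted(IUPAC_SETS[p]) for p in pattern]
    except KeyError as exc:
        raise SequenceError(f"invalid IUPAC code {exc.args[0]!r} in pattern") from exc
    for combo in itertools.product(*sets):
        yield "".join(combo)


def translate(dna: str, frame_start: int = 0) -> str:
    """Standard-code translation starting at ``frame_start``.

    A trailing partial codon is ignored; stop codons render as ``*`` and
    do not terminate translation.
    """
    _check_dna(dna)
    if not 0 <= frame_start < len(dna):
        raise SequenceError(f"frame_start {frame_start} outside sequence")
    coding = dna[frame_start:]
    n = len(coding) - len(coding) % 3
    if n == 0:
        raise SequenceError("no full codon downstream of frame_start")
    return str(Seq(coding[:n]).translate())


def codons_for(aa: str) -> tuple[str, ...]:
    """All codons encoding an amino acid letter (``*`` for stop)."""
    if aa not in CODONS_BY_AA:
        raise SequenceError(f"no codons for amino acid {aa!r}")
    return CODONS_BY_AA[aa]


def min_nt_substitutions(codon_from: str, aa_to: str) -> int:
    """Minimum Hamming distance from ``codon_from`` to any codon of ``aa_to``.

    Zero when the codon already encodes the target residue.
    """
    _check_dna(codon_from, "codon")
    if len(codon_from) != 3:
        raise SequenceError("codon must be 3 nt")
    return min(
        sum(a != b for a, b in zip(codon_from, c)) for c in codons_for(aa_to)
    )


def at_content(dna: str) -> float:
    """Fraction of A+T bases (e.g. the 61.5 % AT of the yeast genome)."""
    _check_dna(dna)
    return (dna.count("A") + dna.count("T")) / len(dna)


@dataclass(frozen=True)
class LocusSequence:
    """A target locus given on its coding (sense) strand.

    Parameters
    ----------
    id : label used in reports.
    seq : unambiguous uppercase DNA; ambiguity codes are rejected so
        reference matching can never silently succeed on a wildcard.
    frame_start : 0-based index of the first base of codon 1 of the ORF.
    sense_strand : flag that ``seq`` is the coding strand (informational).
    """

    id: str
    seq: str
    frame_start: int = 0
    sense_strand: bool = True

    def __post_init__(self) -> None:
        _check_dna(self.seq, f"locus {self.id!r}")
        if self.seq != self.seq.upper():
            raise SequenceError("locus sequence must be uppercase")
        if not 0 <= self.frame_start < len(self.seq):
            raise SequenceError(
                f"frame_start {self.frame_start} outside locus of length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return (len(self.seq) - self.frame_start) // 3

    def codon_interval(self, codon_index: int) -> tuple[int, int]:
        """0-based half-open sense interval of a 1-based codon."""
        if not 1 <= codon_index <= self.n_codons:
            raise SequenceError(
                f"codon {codon_index} outside ORF (1..{self.n_codons})"
            )
        start = self.frame_start + 3 * (codon_index - 1)
        return start, start + 3

    def codon(self, codon_index: int) -> str:
        s, e = self.codon_interval(codon_index)
        return self.seq[s:e]

    def protein(self) -> str:
        return translate(self.seq, self.frame_start)

    def with_seq(self, new_seq: str) -> "LocusSequence":
        return LocusSequence(self.id, new_seq, self.frame_start, self.sense_strand)


@dataclass(frozen=True)
class CodonEdit:
    """An intended codon replacement, e.g. S108N or an explicit codon.

    ``target`` is either a single amino-acid letter (``*`` for stop) or an
    explicit 3-nt codon.
    """

    codon_index: int
    target: str

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise SequenceError("codon_index must be >= 1")
        t = self.target
        if len(t) == 1:
            if t not in AMINO_ACIDS and t != "*":
                raise SequenceError(f"unknown amino acid {t!r}")
        elif len(t) == 3:
            _check_dna(t, "target codon")
        else:
            raise SequenceError("target must be one amino-acid letter or a codon")

    @property
    def is_codon(self) -> bool:
        return len(self.target) == 3

    def target_aa(self) -> str:
        return CODON_TO_AA[self.target] if self.is_codon else self.target


def read_locus(path: str | Path, frame_start: int | None = None) -> LocusSequence:
    """Read a locus from FASTA or GenBank (first record).

    For GenBank, ``frame_start`` defaults to the start of the first CDS
    feature; for FASTA it defaults to 0.
    """
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    record = next(SeqIO.parse(str(path), fmt))
    seq = str(record.seq).upper()
    if frame_start is None:
        frame_start = 0
        if fmt == "genbank":
            for feat in record.features:
                if feat.type == "CDS":
                    frame_start = int(feat.location.start)
                    break
    return LocusSequence(record.id, seq, frame_start)


def write_fasta(loci: Iterable[LocusSequence] | LocusSequence, path: str | Path) -> None:
    if isinstance(loci, LocusSequence):
        loci = [loci]
    records = [SeqRecord(Seq(l.seq), id=l.id, description="") for l in loci]
    SeqIO.write(records, str(path), "fasta")
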