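"""Amplicon-sequencing outcome analysis and its synthetic read generator.

The pipeline mirrors a count-then-percentage scheme for merged amplicon
reads: reads are filtered for the presence of both primers and oriented
to the sense strand; codons are then extracted at fixed frame offsets
from the anchored primer positions (no alignment — reads whose primer
spacing is inconsistent with the reference, e.g. through an indel, fail
anchoring and are tallied separately); counts per position are converted
to percentages of the total at that position. Editing efficiency is the
edited fraction of reads classifiable as wild-type or edited, and
enrichment compares per-codon percentages between a selected and an
untreated population.

Paired-end merging is out of scope: the module consumes merged
single-sequence reads (an external merger such as SeqPrep produces
them from raw paired-end data).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .seqcore import LocusSequence, SequenceError, revcomp

__all__ = [
    "AmpliconSpec",
    "FilterTally",
    "filter_orient",
    "CodonCountTable",
    "count_codons",
    "EfficiencyResult",
    "editing_efficiency",
    "EnrichmentResult",
    "enrichment",
    "simulate_reads",
    "demultiplex",
    "normalize_mic",
    "average_replicates",
    "read_fastq",
    "write_fastq",
]


def _as_str(read) -> str:
    return str(read.seq) if isinstance(read, SeqRecord) else str(read)


@dataclass(frozen=True)
class AmpliconSpec:
    """A sequenced amplicon: sense reference, primer pair, codon window.

    ``fwd_primer`` matches the sense strand; ``rev_primer`` is written as
    it anneals (its reverse complement appears on the sense reference).
    ``frame_start`` is the 0-based index of codon 1 of the reading frame
    within the reference; ``target_codon_range`` is 1-based inclusive.
    ``barcodes`` optionally lists (sample_id, fwd_tag, rev_tag) for
    demultiplexing tagged primer pairs.
    """

    reference: str
    fwd_primer: str
    rev_primer: str
    frame_start: int
    target_codon_range: tuple[int, int]
    barcodes: tuple[tuple[str, str, str], ...] | None = None

    def __post_init__(self) -> None:
        for what, pat in (("fwd_primer", self.fwd_primer), ("rev_primer (rc)", revcomp(self.rev_primer))):
            if self.reference.count(pat) != 1:
                raise SequenceError(f"{what} must occur exactly once in the reference")
        lo, hi = self.target_codon_range
        n_codons = (len(self.reference) - self.frame_start) // 3
        if lo < 1 or hi < lo or hi > n_codons:
            raise SequenceError(
                f"target codon range {self.target_codon_range} outside reference frame"
            )

    def codon_start(self, codon_index: int) -> int:
        return self.frame_start + 3 * (codon_index - 1)

    def window_interval(self) -> tuple[int, int]:
        lo, hi = self.target_codon_range
        return self.codon_start(lo), self.codon_start(hi) + 3

    def wildtype_codon(self, codon_index: int) -> str:
        s = self.codon_start(codon_index)
        return self.reference[s : s + 3]


@dataclass(frozen=True)
class FilterTally:
    n_in: int
    n_pass: int

    @property
    def n_fail(self) -> int:
        return self.n_in - self.n_pass


def _contains(seq: str, pattern: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return pattern in seq
    m = len(pattern)
    for i in range(len(seq) - m + 1):
        if sum(a != b for a, b in zip(seq[i : i + m], pattern)) <= max_mismatch:
            return True
    return False


def filter_orient(
    reads: Iterable, spec: AmpliconSpec, max_mismatch: int = 0
) -> tuple[list[str], FilterTally]:
    """Keep reads carrying both primers; return them sense-oriented.

    A read passes when it contains the forward primer and the reverse
    complement of the reverse primer (sense orientation) or the mirror
    arrangement (antisense, returned reverse-complemented). Idempotent on
    its own output. Failures are tallied, not raised.
    """
    fwd, rev_rc = spec.fwd_primer, revcomp(spec.rev_primer)
    out: list[str] = []
    n_in = 0
    for read in reads:
        n_in += 1
        s = _as_str(read)
        if _contains(s, fwd, max_mismatch) and _contains(s, rev_rc, max_mismatch):
            out.append(s)
            continue
        rc = revcomp(s)
        if _contains(rc, fwd, max_mismatch) and _contains(rc, rev_rc, max_mismatch):
            out.append(rc)
    return out, FilterTally(n_in, len(out))


@dataclass
class CodonCountTable:
    """Per-position codon counts and percentages for the target window."""

    positions: tuple[int, ...]
    counts: dict[int, dict[str, int]]
    wildtype: dict[int, str]
    n_reads_in: int
    n_reads_pass: int
    n_anchor_failed: int
    n_unedited: int  # reads wild-type at every target position

    def total(self, position: int) -> int:
        return sum(self.counts[position].values())

    def percentage(self, position: int, codon: str) -> float:
        t = self.total(position)
        return 100.0 * self.counts[position].get(codon, 0) / t if t else 0.0

    def percentages(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions:
            t = self.total(pos)
            for codon in sorted(self.counts[pos]):
                n = self.counts[pos][codon]
                rows.append(
                    {
                        "position": pos,
                        "codon": codon,
                        "wildtype": codon == self.wildtype[pos],
                        "count": n,
                        "percentage": 100.0 * n / t if t else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def unedited_fraction(self) -> float:
        return self.n_unedited / self.n_reads_pass if self.n_reads_pass else 0.0


def count_codons(oriented_reads: Sequence[str], spec: AmpliconSpec) -> CodonCountTable:
    """Count every codon (wild-type included) over the target window.

    Codons are extracted at fixed offsets from the located forward
    primer; a read must also carry the reverse primer at the
    reference-consistent spacing, so reads with indels between the
    primers fail anchoring and are tallied, never miscounted.
    """
    fwd, rev_rc = spec.fwd_primer, revcomp(spec.rev_primer)
    f_ref = spec.reference.index(fwd)
    span_ref = spec.reference.index(rev_rc) - f_ref
    lo, hi = spec.target_codon_range
    positions = tuple(range(lo, hi + 1))
    counts: dict[int, dict[str, int]] = {p: {} for p in positions}
    wildtype = {p: spec.wildtype_codon(p) for p in positions}
    n_pass = n_fail = n_unedited = 0
    for read in oriented_reads:
        i = read.find(fwd)
        j = read.find(rev_rc)
        if i < 0 or j < 0 or j - i != span_ref:
            n_fail += 1
            continue
        offset = i - f_ref
        codons = {}
        ok = True
        for p in positions:
            s = spec.codon_start(p) + offset
            codon = read[s : s + 3]
            if len(codon) < 3 or set(codon) - set("ACGT"):
                ok = False
                break
            codons[p] = codon
        if not ok:
            n_fail += 1
            continue
        n_pass += 1
        if all(codons[p] == wildtype[p] for p in positions):
            n_unedited += 1
        for p, codon in codons.items():
            counts[p][codon] = counts[p].get(codon, 0) + 1
    return CodonCountTable(
        positions=positions,
        counts=counts,
        wildtype=wildtype,
        n_reads_in=len(oriented_reads),
        n_reads_pass=n_pass,
        n_anchor_failed=n_fail,
        n_unedited=n_unedited,
    )


@dataclass(frozen=True)
class EfficiencyResult:
    n_wildtype: int
    n_edited: int
    n_other: int  # matched neither window: candidate indels / other outcomes

    @property
    def fraction_edited(self) -> float:
        return self.n_edited / (self.n_edited + self.n_wildtype)


def editing_efficiency(
    oriented_reads: Sequence[str], wildtype_window: str, edited_window: str
) -> EfficiencyResult:
    """Edited fraction among reads matching either diagnostic window."""
    if wildtype_window == edited_window:
        raise SequenceError("wild-type and edited windows are identical")
    n_wt = n_ed = n_other = 0
    for read in oriented_reads:
        if wildtype_window in read:
            n_wt += 1
        elif edited_window in read:
            n_ed += 1
        else:
            n_other += 1
    if n_wt + n_ed == 0:
        raise SequenceError("no classifiable reads")
    return EfficiencyResult(n_wt, n_ed, n_other)


@dataclass(frozen=True)
class EnrichmentResult:
    table: pd.DataFrame
    unedited_fraction_treated: float
    unedited_fraction_untreated: float
    pseudo_percentage: float


def enrichment(
    treated: CodonCountTable,
    untreated: CodonCountTable,
    pseudo_percentage: float | None = None,
) -> EnrichmentResult:
    """Per-(position, codon) percentage ratio treated / untreated.

    Codons absent from the untreated table get a pseudo-percentage
    denominator (default: half the smallest positive untreated
    percentage); codons absent from the treated table get ratio 0.
    """
    if treated.positions != untreated.positions:
        raise SequenceError("count tables cover different positions")
    if pseudo_percentage is None:
        positives = [
            untreated.percentage(p, c)
            for p in untreated.positions
            for c in untreated.counts[p]
            if untreated.counts[p][c] > 0
        ]
        pseudo_percentage = min(positives) / 2 if positives else 1e-3
    rows = []
    for p in treated.positions:
        for codon in sorted(set(treated.counts[p]) | set(untreated.counts[p])):
            pt = treated.percentage(p, codon)
            pu = untreated.percentage(p, codon)
            ratio = 0.0 if pt == 0 else pt / (pu if pu > 0 else pseudo_percentage)
            rows.append(
                {
                    "position": p,
                    "codon": codon,
                    "wildtype": codon == treated.wildtype[p],
                    "pct_treated": pt,
                    "pct_untreated": pu,
                    "ratio": ratio,
                }
            )
    return EnrichmentResult(
        table=pd.DataFrame(rows),
        unedited_fraction_treated=treated.unedited_fraction,
        unedited_fraction_untreated=untreated.unedited_fraction,
        pseudo_percentage=pseudo_percentage,
    )


def simulate_reads(
    spec: AmpliconSpec,
    mixture: Sequence[tuple[str, float]],
    n: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Draw merged amplicon reads from a planted window mixture.

    ``mixture`` lists (window DNA, fraction) pairs replacing the target
    window of the reference (substitutions only — same length); reads
    are drawn multinomially, placed on a random strand, and subjected to
    uniform per-base substitution errors. Returns FASTQ-ready records
    (the seed is recorded in each description) plus the planted truth
    counts keyed by window sequence.
    """
    if not 0 <= error_rate <= 0.1:
        raise SequenceError("error_rate must be within [0, 0.1]")
    fracs = np.array([f for _, f in mixture], dtype=float)
    if len(fracs) == 0 or np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise SequenceError("mixture fractions must be non-negative and sum to 1")
    ws, we = spec.window_interval()
    for window, _ in mixture:
        if len(window) != we - ws:
            raise SequenceError("mixture windows must match the target window length")
    rng = np.random.default_rng(seed)
    if n == 0:
        return [], {w: 0 for w, _ in mixture}
    counts = rng.multinomial(n, fracs)
    truth = {w: int(c) for (w, _), c in zip(mixture, counts)}
    records: list[SeqRecord] = []
    bases = np.array(list("ACGT"))
    k = 0
    for (window, _), count in zip(mixture, counts):
        template = spec.reference[:ws] + window + spec.reference[we:]
        for _ in range(count):
            arr = np.array(list(template))
            errs = rng.random(len(arr)) < error_rate
            for idx in np.nonzero(errs)[0]:
                arr[idx] = rng.choice(bases[bases != arr[idx]])
            seq = "".join(arr)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rec = SeqRecord(
                Seq(seq),
                id=f"sim_{seed}_{k}",
                description=f"seed={seed} window={window}",
            )
            rec.letter_annotations["phred_quality"] = [35] * len(seq)
            records.append(rec)
            k += 1
    order = rng.permutation(len(records))
    return [records[i] for i in order], truth


def demultiplex(
    reads: Iterable, spec: AmpliconSpec
) -> dict[str, list[str]]:
    """Partition reads by barcoded primer tags.

    A read is assigned to the first sample whose tagged forward primer
    (fwd_tag + fwd_primer) appears on either strand; the remainder goes
    under ``"unassigned"``. Per-sample counts plus unassigned always sum
    to the input count.
    """
    if not spec.barcodes:
        raise SequenceError("amplicon spec carries no barcodes")
    out: dict[str, list[str]] = {sample: [] for sample, _, _ in spec.barcodes}
    out["unassigned"] = []
    for read in reads:
        s = _as_str(read)
        rc = revcomp(s)
        for sample, ftag, _ in spec.barcodes:
            tagged = ftag + spec.fwd_primer
            if tagged in s or tagged in rc:
                out[sample].append(s)
                break
        else:
            out["unassigned"].append(s)
    return out


def normalize_mic(od_0h: pd.DataFrame, od_48h: pd.DataFrame) -> pd.DataFrame:
    """Drug-resistance growth matrix normalized to no-drug growth.

    Inputs are strain x concentration OD tables at 0 h and 48 h
    (replicates averaged beforehand; see :func:`average_replicates`).
    The 0 h background is subtracted and each strain's row is divided by
    its growth in the 0-concentration column, which therefore equals 1.
    """
    if not od_0h.index.equals(od_48h.index) or not od_0h.columns.equals(od_48h.columns):
        raise SequenceError("0 h and 48 h plates must share strains and concentrations")
    zero_cols = [c for c in od_0h.columns if float(c) == 0.0]
    if not zero_cols:
        raise SequenceError("plate has no 0-concentration column")
    growth = od_48h - od_0h
    baseline = growth[zero_cols[0]]
    bad = baseline[baseline <= 0]
    if len(bad):
        raise SequenceError(
            f"non-positive no-drug growth for strain(s): {', '.join(map(str, bad.index))}"
        )
    return growth.div(baseline, axis=0)


def average_replicates(plates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of replicate OD plates with identical layout."""
    if not plates:
        raise SequenceError("no plates given")
    return sum(plates[1:], start=plates[0].copy()) / len(plates)


def read_fastq(path: str | Path) -> list[SeqRecord]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return list(SeqIO.parse(fh, "fastq"))


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")
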