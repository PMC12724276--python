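"""End-to-end design workflow: guides -> donor -> cassette -> synthesis sheet.

Given a locus and the intended codon edits, the workflow scans and ranks
guide sites, designs the immunized repair donor, assembles the single-
or multi-unit crRNA/donor cassette, and emits Golden Gate oligos plus an
optional NNK library sheet. Outputs are plain text (TSV / GenBank / YAML)
and byte-identical across runs for identical inputs and seed.
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .config import RunConfig
from .donor import (
    DesignError,
    assemble_cassette,
    cassette_to_genbank,
    design_donor,
    donor_to_genbank,
    goldengate_oligos,
)
from .library import nnk_scan
from .pam import builtin_profile, guides_report, rank_guides, scan_guides
from .seqcore import CodonEdit, LocusSequence, SequenceError

__all__ = ["run_workflow", "WorkflowError"]


class WorkflowError(SequenceError):
    """A stage failure, annotated with the stage name and input context."""


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_workflow(
    config: RunConfig,
    locus: LocusSequence,
    edits: Sequence[CodonEdit],
    outdir: str | Path,
    nnk_range: tuple[int, int] | None = None,
) -> dict[str, Path]:
    """Design bundle for a locus and its edits; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = builtin_profile(config.variant_id)
    written: dict[str, Path] = {}

    def _stage(name: str):
        def wrap(exc: Exception) -> WorkflowError:
            return WorkflowError(f"stage {name!r} failed for locus {locus.id!r}: {exc}")

        return wrap

    try:
        sites = scan_guides(
            locus,
            profile,
            min_class="low",
            spacer_len=config.spacer_len,
            cleavage_offset=config.cleavage_offset,
        )
        if not sites:
            raise DesignError("no candidate guide sites at any recognizable PAM")
        ranked = rank_guides(sites, edits[0], locus, config.window_high, config.window_low)
        _log("guides", f"{len(sites)} candidate sites; best: {ranked[0].pam_seq} {ranked[0].strand}")
        report = guides_report(ranked)
        written["guides"] = outdir / "guides.tsv"
        report.to_csv(written["guides"], sep="\t", index=False)
    except (SequenceError, DesignError) as exc:
        raise _stage("guide_scan")(exc) from exc

    try:
        guide = ranked[0]
        donor = design_donor(
            locus, list(edits), guide, profile, arm_length=config.arm_length
        )
        _log("donor", f"{len(donor.edits_applied)} substitution(s), recleavable={donor.recleavable}")
        written["donor"] = outdir / "donor.gb"
        SeqIO.write(donor_to_genbank(donor, f"{locus.id}_donor"), str(written["donor"]), "genbank")
    except (SequenceError, DesignError) as exc:
        raise _stage("donor_design")(exc) from exc

    try:
        cassette = assemble_cassette(
            [(guide.spacer, donor)],
            dr=config.dr_sequence,
            use_separator=config.use_separator,
            parts=config.parts,
        )
        written["cassette"] = outdir / "cassette.gb"
        SeqIO.write(
            cassette_to_genbank(cassette, f"{locus.id}_cassette"),
            str(written["cassette"]),
            "genbank",
        )
    except (SequenceError, DesignError) as exc:
        raise _stage("cassette_assembly")(exc) from exc

    # Synthesis oligos for the guide+donor insert; an internal enzyme site
    # is a user-actionable condition, reported in the sheet rather than fatal.
    insert = config.dr_sequence + guide.spacer + donor.sequence
    written["oligos"] = outdir / "oligos.tsv"
    try:
        oligos = goldengate_oligos(
            insert, enzyme_site=config.enzyme_site, overhangs=config.overhangs
        )
        rows = [
            f"name\tsequence",
            f"{locus.id}_fwd\t{oligos.forward}",
            f"{locus.id}_rev\t{oligos.reverse}",
        ]
    except DesignError as exc:
        _log("oligos", f"skipped: {exc}")
        rows = ["name\tsequence", f"# not emitted: {exc}"]
    written["oligos"].write_text("\n".join(rows) + "\n")

    if nnk_range is not None:
        try:
            lib = nnk_scan(locus, nnk_range, guide)
            written["nnk_constructs"] = outdir / "nnk_constructs.tsv"
            lib.to_frame().to_csv(written["nnk_constructs"], sep="\t", index=False)
            written["nnk_primers"] = outdir / "nnk_primers.tsv"
            lib.primers_frame().to_csv(written["nnk_primers"], sep="\t", index=False)
            _log("library", f"{lib.distinct_constructs} distinct constructs over {lib.region_bp} bp")
        except (SequenceError, DesignError) as exc:
            raise _stage("nnk_library")(exc) from exc

    return written
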