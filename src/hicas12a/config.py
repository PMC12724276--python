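"""Run configuration with the system's printed design constants.

Defaults encode the geometry the design modules are built around:
4-nt PAM, 23-nt spacer, 18 bp PAM-to-cleavage distance, 50 bp homology
arms, and the +-20 bp (high) / 30 bp (declining edge) editing window.
``self_test`` asserts that a config's defaults still equal those
constants, so a drifted or hand-edited config fails loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .pam import available_variants, default_dr
from .seqcore import SequenceError

__all__ = ["RunConfig", "CANONICAL_CONSTANTS"]

#: (cleavage_offset, window_high, window_low, arm_length, spacer_len, pam_len)
CANONICAL_CONSTANTS = {
    "cleavage_offset": 18,
    "window_high": 20,
    "window_low": 30,
    "arm_length": 50,
    "spacer_len": 23,
    "pam_len": 4,
}


@dataclass
class RunConfig:
    variant_id: str = "impLbCas12a"
    spacer_len: int = 23
    arm_length: int = 50
    window_high: int = 20
    window_low: int = 30
    cleavage_offset: int = 18
    pam_len: int = 4
    enzyme_site: str = "GGTCTC"
    overhangs: tuple[str, str] = ("AATG", "GCTT")
    dr: str | None = None  # None -> registry default (20-nt LbCas12a DR)
    use_separator: bool = False
    parts: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.variant_id not in available_variants():
            raise SequenceError(
                f"unknown variant {self.variant_id!r}; known: {', '.join(available_variants())}"
            )
        for name in ("spacer_len", "arm_length", "window_high", "window_low", "cleavage_offset", "pam_len"):
            if getattr(self, name) <= 0:
                raise SequenceError(f"{name} must be positive")
        if self.window_high >= self.window_low:
            raise SequenceError("window_high must be below window_low")
        if not 20 <= self.spacer_len <= 25:
            raise SequenceError("spacer_len must be within 20..25")

    @property
    def dr_sequence(self) -> str:
        return self.dr if self.dr else default_dr()

    def self_test(self) -> None:
        """Assert the geometric defaults equal the canonical constants."""
        for name, value in CANONICAL_CONSTANTS.items():
            found = getattr(RunConfig(), name)
            if found != value:
                raise AssertionError(f"default {name}={found}, expected {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "overhangs" in data:
            data["overhangs"] = tuple(data["overhangs"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["overhangs"] = list(self.overhangs)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
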