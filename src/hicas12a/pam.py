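"""PAM compatibility profiles, guide scanning, and editing-window geometry.

Cas12a reads a 4-nt T-rich PAM 5' of the protospacer and cleaves distally:
the nominal cut sits 18 bp 3' of the PAM, inside the 23-nt spacer-matched
region. Donor-programmed edits incorporate efficiently within roughly
20 bp of the cut on either side and fall off sharply beyond ~30 bp; the
window classifier and the guide ranking encode exactly that geometry.

Per-variant PAM recognition is ordinal (high / moderate / low / none),
loaded from an editable YAML registry. Bar-level efficiencies are
deliberately not encoded — only the class structure supported by the
yeast benchmarking and the prior mammalian / in-vitro reports.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .seqcore import (
    CodonEdit,
    LocusSequence,
    SequenceError,
    expand_iupac,
    iupac_match,
    revcomp,
)

__all__ = [
    "EFFICIENCY_ORDER",
    "PamRule",
    "PamProfile",
    "builtin_profile",
    "available_variants",
    "default_dr",
    "GuideSite",
    "scan_guides",
    "window_class",
    "rank_guides",
    "WindowFit",
    "fit_window_curve",
    "guides_report",
]

EFFICIENCY_ORDER = {"none": 0, "low": 1, "moderate": 2, "high": 3}

PAM_LEN = 4
SPACER_LEN = 23
CLEAVAGE_OFFSET = 18
WINDOW_HIGH = 20
WINDOW_LOW = 30


@dataclass(frozen=True)
class PamRule:
    """One degenerate PAM pattern with its efficiency class and provenance."""

    pattern: str
    efficiency_class: str
    provenance: str

    def __post_init__(self) -> None:
        if len(self.pattern) != PAM_LEN:
            raise SequenceError(f"PAM pattern must be {PAM_LEN} nt: {self.pattern!r}")
        if self.efficiency_class not in EFFICIENCY_ORDER:
            raise SequenceError(f"unknown efficiency class {self.efficiency_class!r}")

    @property
    def degeneracy(self) -> int:
        return math.prod(len(tuple(expand_iupac(c))) for c in self.pattern)

    def matches(self, pam: str) -> bool:
        return iupac_match(self.pattern, pam)


@dataclass(frozen=True)
class PamProfile:
    """A variant's recognizable PAM patterns.

    Classification is deterministic and total over the 256 4-mers:
    exclusion rules are consulted first (carve-outs from broader family
    claims), then the most specific matching entry wins; among equally
    specific entries the higher class wins; an unmatched 4-mer is "none".
    """

    variant_id: str
    entries: tuple[PamRule, ...]
    exclusions: tuple[PamRule, ...] = ()
    notes: str = ""

    def classify_rule(self, pam: str) -> PamRule | None:
        for rule in self.exclusions:
            if rule.matches(pam):
                return rule
        best: PamRule | None = None
        for rule in self.entries:
            if rule.matches(pam):
                if best is None or (rule.degeneracy, -EFFICIENCY_ORDER[rule.efficiency_class]) < (
                    best.degeneracy,
                    -EFFICIENCY_ORDER[best.efficiency_class],
                ):
                    best = rule
        return best

    def classify(self, pam: str) -> str:
        rule = self.classify_rule(pam)
        return rule.efficiency_class if rule else "none"


@lru_cache(maxsize=1)
def _registry() -> dict:
    text = (
        importlib.resources.files("hicas12a") / "data" / "pam_profiles.yaml"
    ).read_text()
    return yaml.safe_load(text)


def available_variants() -> tuple[str, ...]:
    return tuple(_registry()["profiles"])


def default_dr() -> str:
    """Canonical 20-nt LbCas12a direct repeat shipped with the registry."""
    return _registry()["default_dr"]


@lru_cache(maxsize=None)
def builtin_profile(variant_id: str) -> PamProfile:
    """Registry profile for a known Cas12a variant."""
    profiles = _registry()["profiles"]
    if variant_id not in profiles:
        raise KeyError(
            f"unknown variant {variant_id!r}; known: {', '.join(sorted(profiles))}"
        )
    raw = profiles[variant_id]

    def _rules(items: list[dict]) -> tuple[PamRule, ...]:
        return tuple(
            PamRule(d["pattern"], d["class"], d["provenance"]) for d in items or []
        )

    return PamProfile(
        variant_id=variant_id,
        entries=_rules(raw.get("entries")),
        exclusions=_rules(raw.get("exclusions")),
        notes=raw.get("notes", ""),
    )


@dataclass(frozen=True)
class GuideSite:
    """One candidate crRNA target site.

    ``pam_start`` is the 0-based PAM start on the *targeted strand*
    (strand-local coordinates; for the minus strand these index into the
    reverse complement of the locus). ``cleavage_pos`` is the 0-based
    sense-strand coordinate of the nominal cut, 18 nt 3' of the PAM on
    the targeted strand.
    """

    locus_id: str
    strand: str
    pam_start: int
    pam_seq: str
    spacer: str
    cleavage_pos: int
    efficiency_class: str
    locus_len: int
    edit_distance_bp: int | None = None

    @property
    def pam_sense_start(self) -> int:
        if self.strand == "+":
            return self.pam_start
        return self.locus_len - self.pam_start - PAM_LEN

    def pam_sense_interval(self) -> tuple[int, int]:
        s = self.pam_sense_start
        return s, s + PAM_LEN

    def protospacer_sense_interval(self) -> tuple[int, int]:
        local = (self.pam_start + PAM_LEN, self.pam_start + PAM_LEN + len(self.spacer))
        if self.strand == "+":
            return local
        return self.locus_len - local[1], self.locus_len - local[0]

    def staggered_cuts(self, offsets: tuple[int, int] = (18, 23)) -> dict[str, int]:
        """Optional staggered-cut annotation (sense coordinates).

        Cas12a leaves 5' overhangs; the per-strand cut offsets are
        configurable and default to 18 (non-target strand) and 23
        (target strand) nt 3' of the PAM.
        """
        out = {}
        for name, off in zip(("non_target", "target"), offsets):
            local = self.pam_start + PAM_LEN + off
            out[name] = local if self.strand == "+" else self.locus_len - 1 - local
        return out


def scan_guides(
    locus: LocusSequence,
    profile: PamProfile,
    min_class: str = "low",
    spacer_len: int = SPACER_LEN,
    cleavage_offset: int = CLEAVAGE_OFFSET,
) -> list[GuideSite]:
    """All candidate sites on both strands whose PAM classifies >= ``min_class``.

    Deterministic order: ascending sense coordinate of the PAM, plus
    strand before minus. Duplicate spacers within the locus trigger a
    warning (no genome-wide off-target search is attempted).
    """
    if not 20 <= spacer_len <= 25:
        raise SequenceError("spacer_len must be within 20..25")
    if len(locus) < PAM_LEN + spacer_len:
        return []
    min_rank = EFFICIENCY_ORDER[min_class]
    L = len(locus)
    sites: list[GuideSite] = []
    for strand, s in (("+", locus.seq), ("-", revcomp(locus.seq))):
        for p in range(L - PAM_LEN - spacer_len + 1):
            pam = s[p : p + PAM_LEN]
            klass = profile.classify(pam)
            if EFFICIENCY_ORDER[klass] < min_rank:
                continue
            local_cut = p + PAM_LEN + cleavage_offset
            sites.append(
                GuideSite(
                    locus_id=locus.id,
                    strand=strand,
                    pam_start=p,
                    pam_seq=pam,
                    spacer=s[p + PAM_LEN : p + PAM_LEN + spacer_len],
                    cleavage_pos=local_cut if strand == "+" else L - 1 - local_cut,
                    efficiency_class=klass,
                    locus_len=L,
                )
            )
    sites.sort(key=lambda g: (g.pam_sense_start, g.strand == "-"))
    seen: dict[str, int] = {}
    for g in sites:
        seen[g.spacer] = seen.get(g.spacer, 0) + 1
    dupes = [sp for sp, n in seen.items() if n > 1]
    if dupes:
        warnings.warn(
            f"{len(dupes)} spacer(s) occur at multiple sites within {locus.id}",
            stacklevel=2,
        )
    return sites


def window_class(
    distance_bp: int, high: int = WINDOW_HIGH, low: int = WINDOW_LOW
) -> str:
    """Editing-window class of a signed distance from the cleavage site.

    |d| <= 20 bp -> high; 20 < |d| <= 30 -> declining; beyond -> low.
    Symmetric in sign: the window extends both upstream and downstream.
    """
    d = abs(int(distance_bp))
    if d <= high:
        return "high"
    if d <= low:
        return "declining"
    return "low"


_WINDOW_RANK = {"high": 0, "declining": 1, "low": 2}


def _edit_distance(site: GuideSite, interval: tuple[int, int]) -> int:
    """Signed sense-strand bp from the cleavage site to the nearest edited base."""
    s, e = interval
    c = site.cleavage_pos
    if s <= c < e:
        return 0
    return (s - c) if c < s else (e - 1 - c)


def rank_guides(
    sites: Sequence[GuideSite],
    edit: CodonEdit,
    locus: LocusSequence,
    high: int = WINDOW_HIGH,
    low: int = WINDOW_LOW,
) -> list[GuideSite]:
    """Order candidates for a given codon edit.

    Stable sort by window class (high > declining > low), then |distance|
    to the edit, then efficiency class, then ascending sense coordinate.
    """
    if not sites:
        raise SequenceError("no candidate sites to rank")
    interval = locus.codon_interval(edit.codon_index)
    annotated = [replace(g, edit_distance_bp=_edit_distance(g, interval)) for g in sites]
    return sorted(
        annotated,
        key=lambda g: (
            _WINDOW_RANK[window_class(g.edit_distance_bp, high, low)],
            abs(g.edit_distance_bp),
            -EFFICIENCY_ORDER[g.efficiency_class],
            g.pam_sense_start,
        ),
    )


@dataclass(frozen=True)
class WindowFit:
    """Cubic distance-efficiency fit with classical OLS uncertainty.

    ``coef`` holds (a, b, c, e) of y = a + b d + c d^2 + e d^3 in
    ascending powers; ``cov`` is the coefficient covariance matrix.
    """

    coef: np.ndarray
    cov: np.ndarray
    residual_df: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, d) -> np.ndarray:
        X = np.vander(np.asarray(d, dtype=float), 4, increasing=True)
        return X @ self.coef

    def ci_band(self, d, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the fitted mean curve."""
        X = np.vander(np.asarray(d, dtype=float), 4, increasing=True)
        mean = X @ self.coef
        half = stats.t.ppf(0.5 + level / 2, self.residual_df) * np.sqrt(
            np.einsum("ij,jk,ik->i", X, self.cov, X)
        )
        return mean - half, mean + half


def fit_window_curve(points: Iterable[tuple[float, float]]) -> WindowFit:
    """Ordinary-least-squares cubic fit of efficiency against distance.

    Requires at least 5 points and a full-rank cubic design (distances
    not all equal) so a residual degree of freedom remains for the CI.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise SequenceError("need >= 5 (distance, efficiency) points")
    d, y = pts[:, 0], pts[:, 1]
    X = np.vander(d, 4, increasing=True)
    if np.linalg.matrix_rank(X) < 4:
        raise SequenceError("rank-deficient design: distances too degenerate")
    coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - 4
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    return WindowFit(coef=coef, cov=cov, residual_df=df)


def guides_report(sites: Sequence[GuideSite]) -> pd.DataFrame:
    """TSV-ready table of guide sites with 1-based inclusive coordinates."""
    rows = []
    for g in sites:
        s, e = g.pam_sense_interval()
        rows.append(
            {
                "locus": g.locus_id,
                "strand": g.strand,
                "pam_start": s + 1,
                "pam_end": e,
                "pam": g.pam_seq,
                "spacer": g.spacer,
                "cleavage_pos": g.cleavage_pos + 1,
                "efficiency_class": g.efficiency_class,
                "edit_distance_bp": g.edit_distance_bp,
            }
        )
    return pd.DataFrame(rows)
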