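"""Mutation-string handling and Kyte-Doolittle hydropathy profiling.

Variants are written in the field's slash notation, e.g.
``S7N/K63N/I88M/A99E/K113R/I126*`` — each token is wild-type residue,
1-based position, replacement (``*`` = truncation at that residue).  Profiles
are uniform sliding-window means of the Kyte-Doolittle hydropathy constants;
windowed scores below -0.5 mark hydrophilic residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KD_SCALE

from .errors import ValidationError

__all__ = [
    "KD_SCALE",
    "STANDARD_AA",
    "ProteinSeq",
    "Mutation",
    "MutationSpec",
    "HydropathyProfile",
    "parse_mutation_string",
    "apply_mutations",
    "kd_profile",
    "classify_hydrophilic",
    "region_summary",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_TOKEN_RE = re.compile(r"^([A-Z])\s*(\d+)\s*([A-Z*])$")


@dataclass(frozen=True)
class ProteinSeq:
    """A protein chain: identifier plus 1-based one-letter residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValidationError(
                f"non-standard residues {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def at(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self):
            raise ValidationError(f"position {pos} outside sequence of length {len(self)}")
        return self.residues[pos - 1]


class Mutation(NamedTuple):
    wt: str
    pos: int  # 1-based
    new: str  # one-letter code or "*" for truncation

    def __str__(self) -> str:
        return f"{self.wt}{self.pos}{self.new}"


@dataclass(frozen=True)
class MutationSpec:
    """Ordered list of edits; at most one truncation, which must be last."""

    edits: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        positions = [e.pos for e in self.edits]
        if len(set(positions)) != len(positions):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise ValidationError(f"duplicate mutation position(s): {dupes}")
        stops = [e for e in self.edits if e.new == "*"]
        if len(stops) > 1:
            raise ValidationError("at most one truncation (*) allowed")
        if stops and self.edits[-1].new != "*":
            raise ValidationError("truncation (*) must be the last edit")
        if stops and any(e.pos > stops[0].pos for e in self.edits[:-1]):
            raise ValidationError("substitutions beyond the truncation point")

    def __len__(self) -> int:
        return len(self.edits)

    def __str__(self) -> str:
        return "/".join(str(e) for e in self.edits)


def parse_mutation_string(text: str) -> MutationSpec:
    """Parse slash-separated variant notation into a MutationSpec.

    Whitespace inside tokens is tolerated ("S7 N" == "S7N"); edits are
    canonicalized to ascending position order with any truncation last.
    """
    text = text.strip()
    if not text:
        return MutationSpec(edits=())
    edits = []
    for token in text.split("/"):
        m = _TOKEN_RE.match(token.strip())
        if not m:
            raise ValidationError(f"malformed mutation token {token.strip()!r}")
        wt, pos, new = m.group(1), int(m.group(2)), m.group(3)
        if wt not in STANDARD_AA:
            raise ValidationError(f"unknown wild-type residue {wt!r} in {token!r}")
        if new != "*" and new not in STANDARD_AA:
            raise ValidationError(f"unknown replacement residue {new!r} in {token!r}")
        edits.append(Mutation(wt, pos, new))
    edits.sort(key=lambda e: (e.pos, e.new == "*"))
    return MutationSpec(edits=tuple(edits))


def apply_mutations(seq: ProteinSeq, spec: MutationSpec) -> ProteinSeq:
    """Apply substitutions and an optional truncation to a sequence.

    Each edit's wild-type letter must match the sequence; a truncation at
    position p removes residue p and everything downstream (new length p-1).
    """
    residues = list(seq.residues)
    new_len = len(residues)
    for edit in spec.edits:
        if not 1 <= edit.pos <= len(residues):
            raise ValidationError(
                f"mutation position {edit.pos} outside sequence of length {len(residues)}"
            )
        observed = residues[edit.pos - 1]
        if observed != edit.wt:
            raise ValidationError(
                f"wild-type mismatch at {edit.pos}: expected {edit.wt}, sequence has {observed}"
            )
        if edit.new == "*":
            new_len = edit.pos - 1
        else:
            residues[edit.pos - 1] = edit.new
    suffix = f"|{spec}" if len(spec) else ""
    return ProteinSeq(id=f"{seq.id}{suffix}", residues="".join(residues[:new_len]))


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed Kyte-Doolittle scores; NaN where the window would overhang."""

    window: int
    scores: np.ndarray  # len(seq); index i holds the score of residue i+1
    residues: str

    def score_at(self, pos: int) -> float:
        """Windowed score of 1-based residue ``pos`` (NaN near the termini)."""
        if not 1 <= pos <= len(self.residues):
            raise ValidationError(f"position {pos} outside profile")
        return float(self.scores[pos - 1])

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def kd_profile(seq: ProteinSeq, window: int = 9) -> HydropathyProfile:
    """Uniform sliding-window mean of Kyte-Doolittle constants.

    No edge padding: the first and last (window-1)/2 residues have no score.
    """
    if window % 2 == 0:
        raise ValidationError(f"window must be odd, got {window}")
    if not 3 <= window <= len(seq):
        raise ValidationError(
            f"window must be in [3, {len(seq)}] for this sequence, got {window}"
        )
    values = np.array([KD_SCALE[r] for r in seq.residues])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = (window - 1) // 2
    scores = np.full(len(seq), np.nan)
    scores[half : len(seq) - half] = means
    return HydropathyProfile(window=window, scores=scores, residues=seq.residues)


def classify_hydrophilic(profile: HydropathyProfile, threshold: float = -0.5) -> np.ndarray:
    """Boolean mask of residues whose windowed score is strictly below the
    threshold; undefined (edge) positions are False."""
    with np.errstate(invalid="ignore"):
        return np.where(profile.defined, profile.scores < threshold, False)


class RegionSummary(NamedTuple):
    mean_score: float
    n_defined: int
    n_undefined: int


def region_summary(profile: HydropathyProfile, start: int, end: int) -> RegionSummary:
    """Mean windowed score over the 1-based inclusive region [start, end]."""
    n = len(profile.residues)
    if not 1 <= start <= end <= n:
        raise ValidationError(f"region [{start}, {end}] invalid for length {n}")
    segment = profile.scores[start - 1 : end]
    defined = ~np.isnan(segment)
    if not defined.any():
        raise ValidationError(
            f"region [{start}, {end}] contains no positions with defined scores"
        )
    return RegionSummary(
        mean_score=float(np.nanmean(segment)),
        n_defined=int(defined.sum()),
        n_undefined=int((~defined).sum()),
    )
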