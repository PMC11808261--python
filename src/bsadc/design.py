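"""Recombination design: enumerate substitution combinations and screen them
by predicted folding free-energy change.

Candidate combinations are built as the cross product of per-site residue
menus merged with a fixed background (e.g. K63N/I88M/I126*).  A supplied
ddG_fold table (one predicted kcal/mol value per combination; negative =
non-destabilizing under the convention used here) is then ranked ascending and
screened with a strict ``ddG < threshold`` rule.  ddG values are consumed as
data — this package never computes them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataError, ValidationError
from .hydropathy import STANDARD_AA, Mutation, MutationSpec, parse_mutation_string

__all__ = [
    "CombinationCandidate",
    "SiteMenu",
    "enumerate_combinations",
    "load_ddg_table",
    "rank_and_select",
]


@dataclass(frozen=True)
class CombinationCandidate:
    """One recombination candidate with its predicted fold stability change."""

    name: str
    mutation_string: str
    ddG: float  # kcal/mol; negative = stabilizing

    def __post_init__(self) -> None:
        parse_mutation_string(self.mutation_string)  # must be well-formed


@dataclass(frozen=True)
class SiteMenu:
    """Per-site replacement menus plus background edits applied everywhere.

    ``menus`` maps 1-based position -> (wild-type residue, allowed replacements);
    menu residues must differ from the wild type at that site.
    """

    menus: Mapping[int, tuple[str, Sequence[str]]]
    background: MutationSpec = field(default_factory=lambda: MutationSpec(edits=()))

    def __post_init__(self) -> None:
        bg_positions = {e.pos for e in self.background.edits}
        for pos, (wt, choices) in self.menus.items():
            if pos in bg_positions:
                raise ValidationError(
                    f"site {pos} appears in both the menu and the background"
                )
            if wt not in STANDARD_AA:
                raise ValidationError(f"invalid wild-type residue {wt!r} at site {pos}")
            if not choices:
                raise ValidationError(f"empty residue menu at site {pos}")
            for c in choices:
                if c not in STANDARD_AA:
                    raise ValidationError(f"invalid menu residue {c!r} at site {pos}")
                if c == wt:
                    raise ValidationError(
                        f"menu residue {c} at site {pos} equals the wild type"
                    )

    @classmethod
    def from_strings(cls, menus: Sequence[str], background: str = "") -> "SiteMenu":
        """Build from compact CLI notation, e.g. ["S7:NCY", "A99:VET"]."""
        parsed: dict[int, tuple[str, tuple[str, ...]]] = {}
        for item in menus:
            try:
                site, choices = item.split(":")
            except ValueError as exc:
                raise ValidationError(f"menu item {item!r} is not 'S7:NCY'-style") from exc
            wt, pos = site[0], int(site[1:])
            if pos in parsed:
                raise ValidationError(f"site {pos} listed twice")
            parsed[pos] = (wt, tuple(choices))
        return cls(menus=parsed, background=parse_mutation_string(background))


def enumerate_combinations(menu: SiteMenu) -> list[str]:
    """Full cross product of the per-site choices merged with the background.

    Returns canonical mutation strings (sites ascending, truncation last) in
    deterministic lexicographic order; empty menus yield the background alone.
    """
    positions = sorted(menu.menus)
    choice_sets = [
        [(pos, menu.menus[pos][0], c) for c in menu.menus[pos][1]] for pos in positions
    ]
    strings = []
    for combo in itertools.product(*choice_sets):
        edits = [Mutation(wt, pos, new) for pos, wt, new in combo]
        edits.extend(menu.background.edits)
        edits.sort(key=lambda e: (e.pos, e.new == "*"))
        strings.append(str(MutationSpec(edits=tuple(edits))))
    return sorted(strings)


def load_ddg_table(path: str | Path) -> list[CombinationCandidate]:
    """Read a TSV of (name, variants, ddG) rows into validated candidates."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty ddG table", stacklevel=2)
        return []
    required = {"name", "variants", "ddG"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: ddG table has a header but no rows", stacklevel=2)
        return []
    candidates = []
    for i, row in df.iterrows():
        try:
            ddg = float(row["ddG"])
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path} row {i + 1}: non-numeric ddG {row['ddG']!r}") from exc
        if pd.isna(ddg):
            raise DataError(f"{path} row {i + 1}: missing ddG")
        try:
            candidates.append(
                CombinationCandidate(
                    name=str(row["name"]),
                    mutation_string=str(row["variants"]),
                    ddG=ddg,
                )
            )
        except ValidationError as exc:
            raise DataError(f"{path} row {i + 1}: {exc}") from exc
    return candidates


def rank_and_select(
    candidates: Sequence[CombinationCandidate], threshold: float = 0.0
) -> list[CombinationCandidate]:
    """Sort ascending by ddG (ties broken by name) and keep every candidate
    with ddG strictly below the threshold."""
    if not candidates:
        raise ValidationError("no candidates to rank")
    ranked = sorted(candidates, key=lambda c: (c.ddG, c.name))
    return [c for c in ranked if c.ddG < threshold]
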