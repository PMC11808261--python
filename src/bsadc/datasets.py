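"""Published reference values and the synthetic sequence fixture.

Everything here is a small printed table or a constructed stand-in; nothing is
fetched from the network.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

from .design import CombinationCandidate, SiteMenu
from .hydropathy import ProteinSeq

__all__ = [
    "TABLE1_DDG",
    "TABLE2",
    "HALF_LIVES_MIN",
    "SITE_MENU_TEXT",
    "RECOMBINATION_BACKGROUND",
    "table1_candidates",
    "write_table1_tsv",
    "site_menu",
    "synthetic_proprotein",
]

# ddG_fold screen of the eight short-listed recombination candidates
# (variant string, predicted kcal/mol; negative = non-destabilizing).
TABLE1_DDG: tuple[tuple[str, str, float], ...] = (
    ("C1", "S7C/K63N/A99E/K113R", -0.00256648),
    ("C2", "S7C/K63N/A99T/K113R", -0.101781),
    ("N1", "S7N/K63N/A99C/K113R", -0.202330),
    ("N2", "S7N/K63N/A99E/K113E", -0.0948427),
    ("N3", "S7N/K63N/A99E/K113R", -0.543583),
    ("N4", "S7N/K63N/A99T/K113R", -0.388018),
    ("N5", "S7N/K63N/A99V/K113R", -0.241144),
    ("Y1", "S7Y/K63N/A99E/K113R", -0.121693),
)


class VariantKinetics(NamedTuple):
    Km_mM: float
    kcat_per_s: float
    inactivation_rate_per_s: float  # as printed; see note below
    ttn: float


# Published per-variant characterization.  The printed inactivation rate,
# TTN and half-life are mutually inconsistent under any single first-order
# reading (kcat/kinact and ln2/kinact disagree with the TTN and half-life
# columns); this package therefore treats them as independent empirical
# quantities and never forces agreement.
TABLE2: dict[str, VariantKinetics] = {
    "panD-wt": VariantKinetics(3.69, 4.25, 0.0011, 830.56),
    "N3": VariantKinetics(3.22, 8.29, 0.0003, 1676.30),
    "Y1": VariantKinetics(3.82, 7.26, 0.0002, 1685.46),
}

# Reported catalytic half-lives (minutes) from the residual-activity fits.
HALF_LIVES_MIN: dict[str, float] = {"panD-wt": 17.91, "N3": 38.18, "Y1": 60.35}

# Saturation-mutagenesis menus carried into recombination, and the fixed
# background every combination inherits.
SITE_MENU_TEXT: tuple[str, ...] = ("S7:NCY", "A99:VET", "K113:RE")
RECOMBINATION_BACKGROUND = "K63N/I88M/I126*"


def table1_candidates() -> list[CombinationCandidate]:
    return [
        CombinationCandidate(name=n, mutation_string=m, ddG=g) for n, m, g in TABLE1_DDG
    ]


def write_table1_tsv(path: str | Path) -> Path:
    """Materialize the ddG screen as the TSV dialect ``load_ddg_table`` reads."""
    path = Path(path)
    lines = ["name\tvariants\tddG"]
    lines += [f"{n}\t{m}\t{g}" for n, m, g in TABLE1_DDG]
    path.write_text("\n".join(lines) + "\n")
    return path


def site_menu() -> SiteMenu:
    """The recombination design space: 3 x 3 x 2 site menus over the background."""
    return SiteMenu.from_strings(list(SITE_MENU_TEXT), RECOMBINATION_BACKGROUND)


# Residues of the BsADC pro-protein that published work pins to a specific
# 1-based position (region labels, named catalytic/mutated residues, and the
# stretch 5-13 = MMSGKLHRA fixed by the Lys9 hydropathy windows).
_ANCHORS: dict[int, str] = {
    1: "M", 2: "Y", 3: "R", 4: "T",
    5: "M", 6: "M", 7: "S", 8: "G", 9: "K", 10: "L", 11: "H", 12: "R", 13: "A",
    14: "T",
    24: "G", 25: "S",          # pro-protein self-cleavage site
    41: "N", 48: "N",
    52: "G", 58: "Y", 59: "I",  # Y58 proton donor
    63: "K", 68: "V",
    82: "G", 86: "I", 88: "I", 89: "S", 91: "K", 94: "S",
    95: "D", 99: "A", 103: "P", 104: "S", 108: "L", 109: "N",
    113: "K", 117: "M", 126: "I", 127: "L",
}

_FILLER = "AVLEGTDSPQ"  # arbitrary standard residues for unanchored positions
_LENGTH = 127


def synthetic_proprotein() -> ProteinSeq:
    """SYNTHETIC 127-residue stand-in for the BsADC pro-protein.

    The true full-length sequence is not bundled; every residue whose identity
    and position are fixed by the published numbering is anchored (see
    ``_ANCHORS``) and the remainder is arbitrary filler.  All hydropathy
    windows around Lys9 fall entirely inside the anchored 5-13 stretch, so
    window scores there are exact; scores elsewhere are fixture-only.
    """
    residues = [
        _ANCHORS.get(pos, _FILLER[pos % len(_FILLER)]) for pos in range(1, _LENGTH + 1)
    ]
    return ProteinSeq(id="BsADC_proprotein_synthetic", residues="".join(residues))
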