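"""Physicochemical scales for the 20 canonical amino acids.

Defaults are the standard published choices: Kyte–Doolittle (1982)
hydropathy, Zamyatnin (1972) residue volumes (A^3), C-beta branching
(Val/Ile/Thr branch at the beta carbon), and formal side-chain charge at
physiological pH (Lys/Arg +1, Asp/Glu -1, His treated as neutral).  Each
scale is a plain mapping and can be swapped wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._exceptions import ValidationError

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

ZAMYATNIN_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

CBETA_BRANCHING = {aa: (1 if aa in "VIT" else 0) for aa in KYTE_DOOLITTLE}

FORMAL_CHARGE = {
    aa: (1 if aa in "KR" else -1 if aa in "DE" else 0) for aa in KYTE_DOOLITTLE
}


@dataclass(frozen=True)
class AminoAcidScales:
    """Bundle of the four per-residue scales used by the classifier."""

    hydrophobicity: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    volume: dict[str, float] = field(default_factory=lambda: dict(ZAMYATNIN_VOLUME))
    cbeta_branching: dict[str, int] = field(default_factory=lambda: dict(CBETA_BRANCHING))
    formal_charge: dict[str, int] = field(default_factory=lambda: dict(FORMAL_CHARGE))

    def __post_init__(self) -> None:
        residues = set(KYTE_DOOLITTLE)
        for name in ("hydrophobicity", "volume", "cbeta_branching", "formal_charge"):
            scale = getattr(self, name)
            if set(scale) != residues:
                raise ValidationError(f"scale {name!r} must cover exactly the 20 canonical residues")
        if any(not -4.5 <= v <= 4.5 for v in self.hydrophobicity.values()):
            raise ValidationError("hydrophobicity values outside [-4.5, 4.5]")


DEFAULT_SCALES = AminoAcidScales()
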