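"""Core peptide domain types.

A :class:`Peptide` is a validated amino-acid sequence over the 20 canonical
one-letter codes, tagged with its provenance (database record, consensus
template, generated variant, or user input).  :class:`ScaleTable` bundles the
per-residue physical data every descriptor needs — a hydrophobicity scale,
a side-chain/termini pKa set, and average residue masses — loaded from the
plain-text TSV files shipped with the package so alternative scales can be
dropped in.  :class:`HelixGeometry` carries the per-residue rotation angle
used to project a sequence onto a helical wheel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "CANONICAL_AA",
    "Peptide",
    "PeptideSource",
    "ScaleTable",
    "HelixGeometry",
    "PeptideValidationError",
]

#: The 20 canonical amino acids, one-letter codes, alphabetical.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Residue class map used by helical-wheel rendering and face analysis.
#: Partitions the 20 canonical residues.
RESIDUE_CLASSES: dict[str, str] = {
    **{r: "hydrophobic" for r in "ACFILMVW"},
    **{r: "basic" for r in "HKR"},
    **{r: "acidic" for r in "DE"},
    **{r: "polar" for r in "NQSTY"},
    **{r: "special" for r in "GP"},
}

#: Residues treated as hydrophobic when measuring face segregation.
HYDROPHOBIC_AA = frozenset("ACFILMVW")


class PeptideValidationError(ValueError):
    """Raised when a sequence fails canonical-alphabet validation."""


class PeptideSource(str, enum.Enum):
    DATABASE = "database"
    TEMPLATE = "template"
    VARIANT = "variant"
    USER = "user"


def validate_sequence(sequence: str) -> str:
    """Uppercase and validate a sequence; returns the normalized string.

    Raises :class:`PeptideValidationError` naming the first offending
    character and its 0-based position.
    """
    if not sequence:
        raise PeptideValidationError("sequence must be non-empty")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _CANONICAL_SET:
            raise PeptideValidationError(
                f"invalid residue {ch!r} at position {i}: not one of the 20 "
                f"canonical amino acids"
            )
    return seq


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with identifier and provenance.

    Variants must carry ``parent_id`` naming the template they derive from.
    """

    id: str
    sequence: str
    source: PeptideSource = PeptideSource.USER
    parent_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if isinstance(self.source, str):
            object.__setattr__(self, "source", PeptideSource(self.source))
        if self.source is PeptideSource.VARIANT and not self.parent_id:
            raise ValueError(f"variant peptide {self.id!r} requires parent_id")

    def __len__(self) -> int:
        return len(self.sequence)


def _read_tsv_map(path: Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split("\t")
        out[key] = float(val)
    return out


@dataclass(frozen=True)
class ScaleTable:
    """Per-residue physical data backing the descriptor suite.

    ``hydrophobicity`` maps each of the 20 residues to a dimensionless scale
    value; ``pka_side_chain`` covers the ionizable side chains (D, E, C, Y,
    H, K, R); ``residue_mass`` holds average free-amino-acid masses in Da
    (one water is subtracted per peptide bond when summing).
    """

    name: str
    hydrophobicity: dict[str, float]
    pka_side_chain: dict[str, float]
    pka_nterm: float
    pka_cterm: float
    residue_mass: dict[str, float]
    water_mass: float = 18.0153

    def __post_init__(self) -> None:
        for attr in ("hydrophobicity", "residue_mass"):
            missing = _CANONICAL_SET - set(getattr(self, attr))
            if missing:
                raise ValueError(f"{attr} missing residues: {sorted(missing)}")
        if any(v <= 0 for v in self.pka_side_chain.values()) or (
            self.pka_nterm <= 0 or self.pka_cterm <= 0
        ):
            raise ValueError("pKa values must be strictly positive")

    @classmethod
    def default(cls) -> "ScaleTable":
        """Eisenberg consensus hydrophobicity + EMBOSS pKa + average masses."""
        data = resources.files("acpdesign") / "data"
        with resources.as_file(data) as d:
            hyd = _read_tsv_map(d / "eisenberg_hydrophobicity.tsv")
            pka = _read_tsv_map(d / "emboss_pka.tsv")
            mass = _read_tsv_map(d / "residue_masses_avg.tsv")
        return cls(
            name="eisenberg-consensus/emboss",
            hydrophobicity=hyd,
            pka_side_chain={k: v for k, v in pka.items() if len(k) == 1},
            pka_nterm=pka["NTERM"],
            pka_cterm=pka["CTERM"],
            residue_mass=mass,
        )


@dataclass(frozen=True)
class HelixGeometry:
    """Rotation per residue along the helix axis; 100° for an ideal α-helix."""

    delta: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.delta < 360:
            raise ValueError(f"delta must be in (0, 360), got {self.delta}")


_DEFAULT_SCALE: ScaleTable | None = None


def default_scale() -> ScaleTable:
    """Lazily-loaded shared default :class:`ScaleTable`."""
    global _DEFAULT_SCALE
    if _DEFAULT_SCALE is None:
        _DEFAULT_SCALE = ScaleTable.default()
    return _DEFAULT_SCALE
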