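"""Physicochemical descriptor suite for helical peptides.

Implements the characterization layer of the design pipeline: molecular
weight, net charge (integer counting or Henderson–Hasselbalch titration),
mean hydrophobicity, the Eisenberg hydrophobic moment

    μH = (1/N) * | Σ_n H_n exp(i n δ) |,   n = 0..N-1,

helical-wheel projection, hydrophobic face segregation, and a documented
water-solubility heuristic.  All functions are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .peptide import (
    HYDROPHOBIC_AA,
    RESIDUE_CLASSES,
    HelixGeometry,
    Peptide,
    ScaleTable,
    default_scale,
)

__all__ = [
    "DescriptorSet",
    "molecular_weight",
    "net_charge",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "helical_wheel",
    "face_segregation",
    "solubility_estimate",
    "describe",
]

ChargeMode = Literal["integer", "henderson_hasselbalch"]

#: Residues counted toward the hydrophilic fraction of the solubility rule.
_HYDROPHILIC_AA = frozenset("DEKRHNQST")


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical profile of one peptide.

    ``net_charge`` is reported in the mode requested at construction
    (Henderson–Hasselbalch at pH 7 by default).  ``face_segregation`` is the
    maximal fraction of hydrophobic residues falling within one 180° arc of
    the helical wheel; 1.0 means a perfectly segregated hydrophobic face.
    ``solubility`` is a labelled heuristic, not a physical model.
    """

    peptide_id: str
    sequence: str
    length: int
    molecular_weight: float
    net_charge: float
    net_charge_integer: int
    mean_hydrophobicity: float
    hydrophobic_moment: float
    face_segregation: float
    solubility: str

    def as_dict(self) -> dict:
        return asdict(self)


def molecular_weight(peptide: Peptide, scale: ScaleTable | None = None) -> float:
    """Average molecular weight in Da of the free, unmodified peptide.

    Sum of free-amino-acid masses minus one water per peptide bond.
    """
    scale = scale or default_scale()
    seq = peptide.sequence
    total = sum(scale.residue_mass[r] for r in seq)
    return total - (len(seq) - 1) * scale.water_mass


def net_charge(
    peptide: Peptide,
    ph: float = 7.0,
    mode: ChargeMode = "henderson_hasselbalch",
    scale: ScaleTable | None = None,
) -> float:
    """Net charge in elementary charges at the given pH.

    ``integer`` mode counts +1 per K/R and the free N-terminus, −1 per D/E
    and the free C-terminus; histidine counts 0.  The result is pH-independent
    and always a whole number, matching the convention under which designed
    cationic peptides are reported with charges like +7 or +9.

    ``henderson_hasselbalch`` mode titrates every ionizable group with its
    packaged pKa: basic groups (N-terminus, K, R, H) contribute
    ``10^pKa / (10^pKa + 10^pH)`` and acidic groups (C-terminus, D, E, C, Y)
    contribute ``-10^pH / (10^pKa + 10^pH)``.
    """
    if not 0 < ph < 14:
        raise ValueError(f"pH must be in (0, 14), got {ph}")
    seq = peptide.sequence
    if mode == "integer":
        pos = sum(seq.count(r) for r in "KR") + 1  # free N-terminus
        neg = sum(seq.count(r) for r in "DE") + 1  # free C-terminus
        return float(pos - neg)
    if mode != "henderson_hasselbalch":
        raise ValueError(f"unknown charge mode {mode!r}")

    scale = scale or default_scale()

    def basic(pka: float) -> float:
        return 10**pka / (10**pka + 10**ph)

    def acidic(pka: float) -> float:
        return -(10**ph) / (10**pka + 10**ph)

    charge = basic(scale.pka_nterm) + acidic(scale.pka_cterm)
    for r in seq:
        pka = scale.pka_side_chain.get(r)
        if pka is None:
            continue
        charge += basic(pka) if r in "KRH" else acidic(pka)
    return charge


def net_charge_integer(peptide: Peptide) -> int:
    """Integer-mode net charge as an int (convenience wrapper)."""
    return int(net_charge(peptide, mode="integer"))


def mean_hydrophobicity(peptide: Peptide, scale: ScaleTable | None = None) -> float:
    """Mean per-residue hydrophobicity ⟨H⟩ on the packaged scale."""
    scale = scale or default_scale()
    seq = peptide.sequence
    return sum(scale.hydrophobicity[r] for r in seq) / len(seq)


def hydrophobic_moment(
    peptide: Peptide,
    geometry: HelixGeometry | None = None,
    scale: ScaleTable | None = None,
) -> float:
    """Mean hydrophobic moment μH (Eisenberg), dimensionless.

    Each residue's hydrophobicity is placed as a vector at angle n·δ around
    the helix axis; μH is the magnitude of the vector mean.  Zero for a
    sequence whose hydrophobic and hydrophilic residues are angularly
    balanced; bounded above by the largest |H| on the scale.
    """
    geometry = geometry or HelixGeometry()
    scale = scale or default_scale()
    seq = peptide.sequence
    h = np.array([scale.hydrophobicity[r] for r in seq])
    angles = np.deg2rad(geometry.delta) * np.arange(len(seq))
    sum_cos = float(np.dot(h, np.cos(angles)))
    sum_sin = float(np.dot(h, np.sin(angles)))
    return math.hypot(sum_cos, sum_sin) / len(seq)


def helical_wheel(
    peptide: Peptide, geometry: HelixGeometry | None = None
) -> list[tuple[int, str, float, str]]:
    """Project the sequence onto a helical wheel.

    Returns one ``(position, residue, angle_deg, residue_class)`` tuple per
    residue in sequence order; the angle of position n is (n·δ) mod 360 and
    the class is one of hydrophobic / basic / acidic / polar / special.
    """
    geometry = geometry or HelixGeometry()
    return [
        (n, r, (n * geometry.delta) % 360.0, RESIDUE_CLASSES[r])
        for n, r in enumerate(peptide.sequence)
    ]


def face_segregation(
    peptide: Peptide, geometry: HelixGeometry | None = None
) -> float:
    """Fraction of hydrophobic residues capturable by one 180° wheel arc.

    Sweeps half-plane arcs at 1° resolution and returns the maximum fraction
    of the peptide's hydrophobic residues (A, C, F, I, L, M, V, W) whose wheel
    angles fall inside a single arc.  1.0 means a perfectly segregated
    hydrophobic face; a peptide with no hydrophobic residues returns 0 by
    convention.  Requires length ≥ 3.
    """
    if len(peptide) < 3:
        raise ValueError("face_segregation requires peptide length >= 3")
    geometry = geometry or HelixGeometry()
    angles = np.array(
        [
            (n * geometry.delta) % 360.0
            for n, r in enumerate(peptide.sequence)
            if r in HYDROPHOBIC_AA
        ]
    )
    if angles.size == 0:
        return 0.0
    # count residues in the half-open arc [start, start + 180) for every
    # integer start; vectorized over all 360 arc positions at once
    starts = np.arange(360.0)
    offsets = (angles[None, :] - starts[:, None]) % 360.0
    best = int((offsets < 180.0).sum(axis=1).max())
    return best / angles.size


def solubility_estimate(peptide: Peptide, scale: ScaleTable | None = None) -> str:
    """Water-solubility class by a documented heuristic: ``good`` or ``poor``.

    ``good`` iff the hydrophilic-residue fraction (D, E, K, R, H, N, Q, S, T)
    is at least 0.25 AND the integer-mode net charge has magnitude ≥ 1.
    A coarse screen, labelled heuristic wherever reported.
    """
    seq = peptide.sequence
    frac = sum(1 for r in seq if r in _HYDROPHILIC_AA) / len(seq)
    charge = net_charge(peptide, mode="integer")
    return "good" if frac >= 0.25 and abs(charge) >= 1 else "poor"


def describe(
    peptide: Peptide,
    geometry: HelixGeometry | None = None,
    scale: ScaleTable | None = None,
    ph: float = 7.0,
    charge_mode: ChargeMode = "henderson_hasselbalch",
) -> DescriptorSet:
    """Aggregate the full descriptor suite into one record.

    Pure and deterministic: identical inputs give identical outputs.
    ``face_segregation`` is reported as 0.0 for peptides shorter than 3
    residues (the arc scan is undefined there).
    """
    geometry = geometry or HelixGeometry()
    scale = scale or default_scale()
    seg = face_segregation(peptide, geometry) if len(peptide) >= 3 else 0.0
    return DescriptorSet(
        peptide_id=peptide.id,
        sequence=peptide.sequence,
        length=len(peptide),
        molecular_weight=molecular_weight(peptide, scale),
        net_charge=net_charge(peptide, ph=ph, mode=charge_mode, scale=scale),
        net_charge_integer=int(net_charge(peptide, mode="integer")),
        mean_hydrophobicity=mean_hydrophobicity(peptide, scale),
        hydrophobic_moment=hydrophobic_moment(peptide, geometry, scale),
        face_segregation=seg,
        solubility=solubility_estimate(peptide, scale),
    )
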