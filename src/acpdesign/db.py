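"""Sequence-database ingestion and consensus-template derivation.

Loads a peptide database (FASTA or delimited table), bins it by length,
stacks the equal-length sequences into positional frequency matrices (no
gapped alignment is needed because each bin shares a length), and extracts
one consensus template per length: the argmax residue at every position,
with per-position information content IC_j = log2(20) − H(column j) reported
for diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .peptide import (
    CANONICAL_AA,
    Peptide,
    PeptideSource,
    PeptideValidationError,
)

__all__ = [
    "PeptideDB",
    "PositionFrequencyMatrix",
    "ConsensusTemplate",
    "load_database",
    "filter_by_length",
    "build_pfm",
    "consensus_template",
    "derive_templates",
]

logger = logging.getLogger(__name__)

_AA_INDEX = {r: i for i, r in enumerate(CANONICAL_AA)}
LOG2_20 = float(np.log2(20))


@dataclass
class PeptideDB:
    """A collection of validated peptides plus load metadata."""

    records: list[Peptide]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = Counter(len(p) for p in self.records)
        self.metadata.setdefault("counts_per_length", dict(sorted(counts.items())))
        seqs = Counter(p.sequence for p in self.records)
        dupes = {s: n for s, n in seqs.items() if n > 1}
        if dupes and not self.metadata.get("deduplicated"):
            self.metadata.setdefault("duplicate_sequences", len(dupes))

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.records]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue counts for one fixed-length sequence bin.

    ``counts`` has shape (length, 20) with columns ordered alphabetically by
    one-letter code; every row sums to ``n_sequences``.
    """

    length: int
    counts: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_sequences < 1:
            raise ValueError("PFM requires length >= 1 and n_sequences >= 1")
        if self.counts.shape != (self.length, 20):
            raise ValueError(f"counts shape {self.counts.shape} != ({self.length}, 20)")
        if not np.all(self.counts.sum(axis=1) == self.n_sequences):
            raise ValueError("every PFM column must sum to n_sequences")

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, columns=list(CANONICAL_AA),
            index=pd.RangeIndex(self.length, name="position"),
        )


@dataclass(frozen=True)
class ConsensusTemplate:
    """Argmax-per-position consensus for one length bin."""

    peptide: Peptide
    length: int
    information_content: np.ndarray  # bits per position
    support: int

    def __post_init__(self) -> None:
        ic = self.information_content
        if np.any(ic < -1e-12) or np.any(ic > LOG2_20 + 1e-12):
            raise ValueError("information content out of [0, log2 20]")


def _iter_fasta(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _iter_table(path: Path, delimiter: str | None) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep=delimiter, engine="python")
    df.columns = [c.lower() for c in df.columns]
    if "sequence" not in df.columns:
        raise ValueError(f"table {path} is missing the required 'sequence' column")
    ids = df["id"] if "id" in df.columns else pd.Series(
        [f"rec{i}" for i in range(len(df))]
    )
    return list(zip(ids.astype(str), df["sequence"].astype(str)))


def load_database(
    path: str | Path,
    format: str = "fasta",
    dedupe: bool = False,
    strict: bool = False,
    delimiter: str | None = None,
) -> PeptideDB:
    """Load a peptide database from FASTA or a delimited table.

    Sequences are uppercased and validated against the canonical alphabet.
    Records failing validation are skipped with a warning, or abort the load
    when ``strict`` is set.  ``dedupe`` collapses exact duplicate sequences
    (first occurrence wins); off by default because database redundancy is
    treated as part of the compositional signal.
    """
    path = Path(path)
    if format == "fasta":
        raw = _iter_fasta(path)
    elif format == "table":
        raw = _iter_table(path, delimiter)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'table'")

    records: list[Peptide] = []
    skipped: list[str] = []
    for rec_id, seq in raw:
        try:
            records.append(Peptide(rec_id, seq, PeptideSource.DATABASE))
        except PeptideValidationError as exc:
            if strict:
                raise PeptideValidationError(
                    f"record {rec_id!r}: {exc}"
                ) from exc
            skipped.append(rec_id)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} invalid records: {skipped[:10]}",
            stacklevel=2,
        )
    if not records:
        raise ValueError(f"no valid records loaded from {path}")

    meta: dict = {"source": str(path), "format": format, "n_skipped": len(skipped)}
    if dedupe:
        seen: set[str] = set()
        unique = []
        for p in records:
            if p.sequence not in seen:
                seen.add(p.sequence)
                unique.append(p)
        meta["deduplicated"] = True
        meta["n_duplicates_removed"] = len(records) - len(unique)
        records = unique
    db = PeptideDB(records, meta)
    logger.info("loaded %d peptides from %s", len(db), path)
    return db


def filter_by_length(db: PeptideDB, min_len: int = 15, max_len: int = 20) -> PeptideDB:
    """Retain records with min_len ≤ length ≤ max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [p for p in db.records if min_len <= len(p) <= max_len]
    if not kept:
        warnings.warn(
            f"length filter [{min_len}, {max_len}] retained no records",
            stacklevel=2,
        )
    meta = {**db.metadata, "length_filter": (min_len, max_len)}
    meta.pop("counts_per_length", None)
    return PeptideDB(kept, meta)


def build_pfm(db: PeptideDB, length: int) -> PositionFrequencyMatrix:
    """Count residues per position across all sequences of exactly ``length``."""
    seqs = [s for s in db.sequences() if len(s) == length]
    if not seqs:
        raise ValueError(f"no sequences of length {length} in database")
    idx = np.array([[_AA_INDEX[r] for r in s] for s in seqs])
    counts = np.zeros((length, 20), dtype=np.int64)
    for j in range(length):
        np.add.at(counts[j], idx[:, j], 1)
    return PositionFrequencyMatrix(length, counts, len(seqs))


def column_information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """IC_j = log2(20) − Shannon entropy of column j, in bits (0·log0 ≡ 0)."""
    freq = pfm.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    return LOG2_20 - entropy


def consensus_template(
    pfm: PositionFrequencyMatrix, template_id: str | None = None
) -> ConsensusTemplate:
    """Extract the argmax-per-position consensus from a PFM.

    Ties are broken lexicographically by one-letter code (the column order of
    the PFM), making extraction deterministic.  No small-sample correction is
    applied to the information content.
    """
    # np.argmax takes the first maximum; columns are in alphabetical order,
    # which is exactly the documented lexicographic tie-break.
    residues = [CANONICAL_AA[i] for i in np.argmax(pfm.counts, axis=1)]
    seq = "".join(residues)
    pid = template_id or f"T{pfm.length}"
    return ConsensusTemplate(
        peptide=Peptide(pid, seq, PeptideSource.TEMPLATE),
        length=pfm.length,
        information_content=column_information_content(pfm),
        support=pfm.n_sequences,
    )


def derive_templates(
    db: PeptideDB, min_len: int = 15, max_len: int = 20
) -> list[ConsensusTemplate]:
    """One consensus template per supported length, ordered ascending.

    Lengths in the window with zero sequences are skipped with a warning.
    """
    templates: list[ConsensusTemplate] = []
    lengths = {len(p) for p in db.records}
    for length in range(min_len, max_len + 1):
        if length not in lengths:
            warnings.warn(f"no sequences of length {length}; skipped", stacklevel=2)
            continue
        templates.append(consensus_template(build_pfm(db, length)))
    return templates


def templates_to_fasta(templates: list[ConsensusTemplate], path: str | Path) -> None:
    """Write consensus templates as FASTA."""
    with open(path, "w") as fh:
        for t in templates:
            fh.write(f">{t.peptide.id} length={t.length} support={t.support}\n")
            fh.write(t.peptide.sequence + "\n")
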