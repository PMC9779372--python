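"""Synthetic peptide corpora with planted consensus structure.

Real anticancer-peptide databases cannot be redistributed here, so testing
runs on generated look-alikes: for each length bin a *planted consensus*
sequence is fixed, and every synthetic peptide draws each position i.i.d. —
the planted residue with probability ``match_probability`` (default 0.6),
otherwise a background residue.  The background is uniform over the other 19
residues except that lysine and arginine are up-weighted by a cationic
enrichment factor, mirroring the compositional bias of known anticancer
peptides (rich in cationic and hydrophobic residues).  Everything is seeded
and byte-reproducible; the planted truth is recorded in the database
metadata so consensus recovery can be checked against it.

A companion generator emits synthetic predictor-score tables whose columns
are documented monotone functions of charge / hydrophobicity plus seeded
Gaussian noise, for exercising the external-score import path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .db import PeptideDB
from .descriptors import mean_hydrophobicity, net_charge
from .peptide import CANONICAL_AA, Peptide, PeptideSource

__all__ = ["PlantedModel", "generate_mock_db", "generate_score_table"]

_AA = np.array(list(CANONICAL_AA))
_AA_INDEX = {r: i for i, r in enumerate(CANONICAL_AA)}

#: Residues favoured when drawing planted consensus sequences: the cationic
#: and hydrophobic residues typical of anticancer peptides.
_CONSENSUS_POOL = "KKRRLLIIFAVWGSA"


@dataclass(frozen=True)
class PlantedModel:
    """Generative model for a CancerPPD-like corpus.

    ``planted_consensus`` maps length → the true consensus sequence; when
    absent one is drawn per length from a K/R- and hydrophobe-enriched pool
    using ``seed``.  ``match_probability`` is the per-position chance of
    emitting the planted residue; the remaining mass goes to a background
    over the other 19 residues, uniform except K/R up-weighted by
    ``cationic_enrichment``.
    """

    min_len: int = 15
    max_len: int = 20
    n_per_length: int = 200
    match_probability: float = 0.6
    cationic_enrichment: float = 3.0
    seed: int = 0
    planted_consensus: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.match_probability <= 1:
            raise ValueError("match_probability must be in (0, 1]")
        if self.cationic_enrichment <= 0:
            raise ValueError("cationic_enrichment must be positive")
        if self.min_len > self.max_len or self.min_len < 1:
            raise ValueError("invalid length range")
        if self.n_per_length < 1:
            raise ValueError("n_per_length must be >= 1")

    def consensus_for(self, rng: np.random.Generator) -> dict[int, str]:
        if self.planted_consensus is not None:
            return dict(self.planted_consensus)
        pool = np.array(list(_CONSENSUS_POOL))
        return {
            length: "".join(rng.choice(pool, size=length))
            for length in range(self.min_len, self.max_len + 1)
        }


def _background_probs(planted_residue: str, enrichment: float) -> np.ndarray:
    """Distribution over the 19 non-planted residues, K/R up-weighted."""
    w = np.ones(20)
    w[_AA_INDEX["K"]] = enrichment
    w[_AA_INDEX["R"]] = enrichment
    w[_AA_INDEX[planted_residue]] = 0.0
    return w / w.sum()


def generate_mock_db(
    model: PlantedModel, fasta_path: str | Path | None = None
) -> PeptideDB:
    """Draw a synthetic peptide database from the planted model.

    Bit-reproducible from ``model.seed``; the planted consensus per length is
    stored in ``metadata["planted_consensus"]``.  Optionally also writes the
    corpus as FASTA.
    """
    rng = np.random.default_rng(model.seed)
    consensus = model.consensus_for(rng)
    p = model.match_probability
    records: list[Peptide] = []
    for length in range(model.min_len, model.max_len + 1):
        planted = consensus[length]
        # per-position emission distribution: planted residue with prob p,
        # background otherwise
        probs = np.empty((length, 20))
        for j, res in enumerate(planted):
            bg = _background_probs(res, model.cationic_enrichment)
            probs[j] = (1 - p) * bg
            probs[j, _AA_INDEX[res]] += p
        # vectorized categorical sampling: inverse-CDF per position
        cum = np.cumsum(probs, axis=1)
        u = rng.random((model.n_per_length, length))
        idx = (u[:, :, None] >= cum[None, :, :]).sum(axis=-1)
        for i in range(model.n_per_length):
            seq = "".join(_AA[idx[i]])
            records.append(
                Peptide(f"synth_L{length}_{i}", seq, PeptideSource.DATABASE)
            )
    db = PeptideDB(
        records,
        {
            "source": "synthetic-planted-model",
            "seed": model.seed,
            "match_probability": p,
            "planted_consensus": consensus,
        },
    )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for pep in db.records:
                fh.write(f">{pep.id}\n{pep.sequence}\n")
    return db


@dataclass(frozen=True)
class ScoreCoupling:
    """How synthetic tool scores track peptide features.

    Anticancer/CPP columns rise with integer net charge, hemolysis columns
    rise with mean hydrophobicity; all are logistic in the feature, centred
    at ``charge_mid`` / ``hydrophobicity_mid``, with i.i.d. Gaussian noise of
    standard deviation ``noise_sigma`` added before clipping to [0, 1].
    """

    charge_mid: float = 5.0
    hydrophobicity_mid: float = 0.0
    slope: float = 0.8
    noise_sigma: float = 0.05


def generate_score_table(
    db: PeptideDB,
    coupling: ScoreCoupling | None = None,
    seed: int = 0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Synthetic nine-tool predictor table for every sequence in the db."""
    coupling = coupling or ScoreCoupling()
    rng = np.random.default_rng(seed)
    seqs = db.sequences()
    charges = np.array(
        [net_charge(p, mode="integer") for p in db.records]
    )
    hydroph = np.array([mean_hydrophobicity(p) for p in db.records])

    def squash(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-coupling.slope * x))

    base_act = squash(charges - coupling.charge_mid)
    base_hem = squash(hydroph - coupling.hydrophobicity_mid)
    cols: dict[str, np.ndarray] = {"sequence": np.array(seqs)}
    for name in ("mACPpred", "ACPred", "ENNACT", "CellPPD", "BchemRF_CPPred", "MLCPP"):
        noise = rng.normal(0, coupling.noise_sigma, len(seqs))
        cols[name] = np.clip(base_act + noise, 0.0, 1.0)
    for name in ("HAPPENN", "DBAASP", "HemoPI"):
        noise = rng.normal(0, coupling.noise_sigma, len(seqs))
        cols[name] = np.clip(base_hem + noise, 0.0, 1.0)
    df = pd.DataFrame(cols)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
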