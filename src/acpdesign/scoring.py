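"""Activity scoring and candidate ranking.

The design pipeline screens variants for three properties — anticancer
potential, cell penetration, and hemolytic risk — originally assessed with
black-box web predictors whose models are not published.  Here each category
gets a transparent *surrogate*: a logistic squash of a linear combination of
interpretable physicochemical features (net charge, hydrophobic moment,
K/R content, mean hydrophobicity, face segregation), monotone in the
features the literature associates with each activity.  Real predictor
outputs, when available, can be imported from delimited tables and take the
surrogates' place.

The overall score aggregates the three categories as

    overall = w_ac * anticancer + w_cpp * cell_penetration
              + w_hem * (1 - hemolysis)

so that low hemolytic risk is rewarded; weights default to equal thirds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .descriptors import (
    describe,
    face_segregation,
    hydrophobic_moment,
    mean_hydrophobicity,
    net_charge,
)
from .peptide import HYDROPHOBIC_AA, HelixGeometry, Peptide, ScaleTable
from .variants import VariantSet

__all__ = [
    "ActivityScores",
    "ScorePolicy",
    "score_anticancer",
    "score_cell_penetration",
    "score_hemolysis",
    "score_activities",
    "import_external_scores",
    "aggregate",
    "rank_candidates",
]


@dataclass(frozen=True)
class ActivityScores:
    """Per-category activity scores in [0, 1]; hemolysis is a risk score."""

    anticancer: float
    cell_penetration: float
    hemolysis: float
    provenance: str = "surrogate"  # or "imported"

    def __post_init__(self) -> None:
        for name in ("anticancer", "cell_penetration", "hemolysis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} score {v} outside [0, 1]")


def _default_midpoints() -> dict[str, float]:
    return {
        "charge": 5.0,
        "moment": 0.3,
        "kr_fraction": 0.3,
        "hydrophobicity": 0.2,
        "r_fraction": 0.15,
        "face_segregation": 0.75,
        "hydrophobic_fraction": 0.45,
    }


def _default_slopes() -> dict[str, float]:
    return {
        "charge": 0.5,
        "moment": 3.0,
        "kr_fraction": 3.0,
        "hydrophobicity": 3.0,
        "r_fraction": 4.0,
        "face_segregation": 2.0,
        "hydrophobic_fraction": 3.0,
        "length_penalty": 0.5,
    }


@dataclass(frozen=True)
class ScorePolicy:
    """Weights and surrogate feature midpoints/slopes.

    Weights are normalized to sum to 1.  A peptide whose features sit exactly
    at the midpoints scores 0.5 in every surrogate (logistic midpoint).  The
    length window [min_len, max_len] only matters through a penalty on
    residues outside it in the anticancer surrogate.
    """

    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    midpoints: dict[str, float] = field(default_factory=_default_midpoints)
    slopes: dict[str, float] = field(default_factory=_default_slopes)
    min_len: int = 15
    max_len: int = 20

    def __post_init__(self) -> None:
        w = self.weights
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        total = sum(w)
        object.__setattr__(self, "weights", tuple(x / total for x in w))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _length_deviation(n: int, policy: ScorePolicy) -> int:
    if n < policy.min_len:
        return policy.min_len - n
    if n > policy.max_len:
        return n - policy.max_len
    return 0


def score_anticancer(
    peptide: Peptide,
    policy: ScorePolicy | None = None,
    scale: ScaleTable | None = None,
    geometry: HelixGeometry | None = None,
) -> float:
    """Surrogate anticancer score in [0, 1].

    Logistic squash of integer net charge, hydrophobic moment, and K/R
    fraction (each centred on its policy midpoint), minus a penalty for
    lengths outside the design window.  Monotone non-decreasing in charge
    and hydrophobic moment with the other features fixed.
    """
    policy = policy or ScorePolicy()
    seq = peptide.sequence
    m, s = policy.midpoints, policy.slopes
    z = net_charge(peptide, mode="integer")
    mu = hydrophobic_moment(peptide, geometry, scale)
    kr = sum(1 for r in seq if r in "KR") / len(seq)
    x = (
        s["charge"] * (z - m["charge"])
        + s["moment"] * (mu - m["moment"])
        + s["kr_fraction"] * (kr - m["kr_fraction"])
        - s["length_penalty"] * _length_deviation(len(seq), policy)
    )
    return _sigmoid(x)


def score_cell_penetration(
    peptide: Peptide,
    policy: ScorePolicy | None = None,
    scale: ScaleTable | None = None,
    geometry: HelixGeometry | None = None,
) -> float:
    """Surrogate cell-penetration score: charge, arginine content, and
    helical amphipathicity (face segregation); monotone in net charge."""
    policy = policy or ScorePolicy()
    seq = peptide.sequence
    m, s = policy.midpoints, policy.slopes
    z = net_charge(peptide, mode="integer")
    rf = seq.count("R") / len(seq)
    seg = face_segregation(peptide, geometry) if len(seq) >= 3 else 0.0
    x = (
        s["charge"] * (z - m["charge"])
        + s["r_fraction"] * (rf - m["r_fraction"])
        + s["face_segregation"] * (seg - m["face_segregation"])
    )
    return _sigmoid(x)


def score_hemolysis(
    peptide: Peptide,
    policy: ScorePolicy | None = None,
    scale: ScaleTable | None = None,
    geometry: HelixGeometry | None = None,
) -> float:
    """Surrogate hemolytic *risk* in [0, 1]; higher means more hemolytic.

    Driven by mean hydrophobicity, hydrophobic moment, and hydrophobic
    residue fraction; monotone non-decreasing in mean hydrophobicity."""
    policy = policy or ScorePolicy()
    seq = peptide.sequence
    m, s = policy.midpoints, policy.slopes
    h = mean_hydrophobicity(peptide, scale)
    mu = hydrophobic_moment(peptide, geometry, scale)
    hf = sum(1 for r in seq if r in HYDROPHOBIC_AA) / len(seq)
    x = (
        s["hydrophobicity"] * (h - m["hydrophobicity"])
        + s["moment"] * (mu - m["moment"])
        + s["hydrophobic_fraction"] * (hf - m["hydrophobic_fraction"])
    )
    return _sigmoid(x)


def score_activities(
    peptide: Peptide,
    policy: ScorePolicy | None = None,
    scale: ScaleTable | None = None,
    geometry: HelixGeometry | None = None,
) -> ActivityScores:
    """All three surrogate scores for one peptide."""
    return ActivityScores(
        anticancer=score_anticancer(peptide, policy, scale, geometry),
        cell_penetration=score_cell_penetration(peptide, policy, scale, geometry),
        hemolysis=score_hemolysis(peptide, policy, scale, geometry),
        provenance="surrogate",
    )


#: Default mapping from predictor-tool column names to score categories.
DEFAULT_TOOL_CATEGORIES: dict[str, str] = {
    "macppred": "anticancer",
    "acpred": "anticancer",
    "ennact": "anticancer",
    "cellppd": "cell_penetration",
    "bchemrf_cpppred": "cell_penetration",
    "mlcpp": "cell_penetration",
    "happenn": "hemolysis",
    "dbaasp": "hemolysis",
    "hemopi": "hemolysis",
}


def import_external_scores(
    path: str | Path,
    tool_column_map: dict[str, str] | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    delimiter: str | None = None,
) -> dict[str, ActivityScores]:
    """Read predictor outputs from a delimited table keyed by sequence.

    ``tool_column_map`` maps column names (lowercased) to one of
    ``anticancer`` / ``cell_penetration`` / ``hemolysis``; multiple tools per
    category are averaged.  ``ranges`` optionally declares a per-column
    (min, max) for min-max rescaling to [0, 1]; columns without a declared
    range must already lie in [0, 1] and raise a range error (naming the
    offending row) otherwise.  Categories with no mapped column default to a
    neutral 0.5.  Returns an empty map (with a warning) for an empty table.
    """
    tool_column_map = tool_column_map or DEFAULT_TOOL_CATEGORIES
    ranges = ranges or {}
    df = pd.read_csv(path, sep=delimiter, engine="python")
    df.columns = [c.lower() for c in df.columns]
    if "sequence" not in df.columns:
        raise ValueError("score table is missing the required 'sequence' column")
    mapped = {c: cat for c, cat in tool_column_map.items() if c in df.columns}
    if df.empty:
        warnings.warn("empty score table; no external scores imported", stacklevel=2)
        return {}
    if not mapped:
        raise ValueError(
            f"no mappable score columns; table has {list(df.columns)}"
        )

    for col in mapped:
        lo, hi = ranges.get(col, (0.0, 1.0))
        vals = df[col].astype(float)
        bad = df.index[(vals < lo) | (vals > hi)]
        if len(bad):
            i = int(bad[0])
            raise ValueError(
                f"column {col!r} value {vals[i]} in row {i} outside declared "
                f"range [{lo}, {hi}]"
            )
        if (lo, hi) != (0.0, 1.0):
            df[col] = (vals - lo) / (hi - lo)

    out: dict[str, ActivityScores] = {}
    for _, row in df.iterrows():
        cat_scores: dict[str, list[float]] = {}
        for col, cat in mapped.items():
            cat_scores.setdefault(cat, []).append(float(row[col]))
        means = {c: sum(v) / len(v) for c, v in cat_scores.items()}
        out[str(row["sequence"]).upper()] = ActivityScores(
            anticancer=means.get("anticancer", 0.5),
            cell_penetration=means.get("cell_penetration", 0.5),
            hemolysis=means.get("hemolysis", 0.5),
            provenance="imported",
        )
    return out


def aggregate(scores: ActivityScores, policy: ScorePolicy | None = None) -> float:
    """Overall score in [0, 1]: weighted anticancer + CPP + (1 − hemolysis)."""
    policy = policy or ScorePolicy()
    w_ac, w_cpp, w_hem = policy.weights
    return (
        w_ac * scores.anticancer
        + w_cpp * scores.cell_penetration
        + w_hem * (1.0 - scores.hemolysis)
    )


def rank_candidates(
    variants: VariantSet,
    policy: ScorePolicy | None = None,
    scale: ScaleTable | None = None,
    geometry: HelixGeometry | None = None,
    external_scores: dict[str, ActivityScores] | None = None,
) -> pd.DataFrame:
    """Score, aggregate, and rank a variant set into a candidate table.

    Rows are sorted by overall score descending; exact ties fall back to
    lower hemolysis, then lexicographic sequence, so the ordering is total,
    stable, and invariant to input permutation.  Each row carries the full
    descriptor set, per-category scores, and the substitution record.
    Sequences present in ``external_scores`` use the imported values instead
    of the surrogates.
    """
    policy = policy or ScorePolicy()
    if len(variants) == 0:
        warnings.warn("empty variant set; empty report", stacklevel=2)
        return pd.DataFrame()
    rows = []
    for pep, subs in zip(variants.variants, variants.substitutions):
        desc = describe(pep, geometry, scale)
        if external_scores and pep.sequence in external_scores:
            act = external_scores[pep.sequence]
        else:
            act = score_activities(pep, policy, scale, geometry)
        rows.append(
            {
                **desc.as_dict(),
                "parent_id": pep.parent_id,
                "substitutions": ";".join(f"{f}{p}{t}" for p, f, t in subs),
                "anticancer": act.anticancer,
                "cell_penetration": act.cell_penetration,
                "hemolysis": act.hemolysis,
                "score_provenance": act.provenance,
                "overall": aggregate(act, policy),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["overall", "hemolysis", "sequence"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", df.index + 1)
    return df
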