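"""Combinatorial K/R substitution of consensus templates.

Candidate peptides are produced by replacing up to ``k_max`` residues of a
template with lysine (K) or arginine (R).  The target set at each position is
{K, R} minus the residue already there, so K↔R swaps are allowed but no-op
substitutions are excluded; every emitted variant therefore differs from its
template at between 1 and ``k_max`` positions, and all differing positions
hold K or R.  Exhaustive enumeration covers the whole space (closed-form
count Σ_k Σ_{|S|=k} Π_{j∈S} |choices_j|); sampled mode draws uniformly
without replacement from that same space, reproducibly from a seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .peptide import Peptide, PeptideSource

__all__ = [
    "EnumerationConfig",
    "VariantSet",
    "Substitution",
    "substitutable_choices",
    "count_variants",
    "enumerate_variants",
    "apply_modification",
]

#: Exhaustive enumeration refuses above this predicted variant count.
EXHAUSTIVE_SAFETY_BOUND = 5_000_000

Substitution = tuple[int, str, str]  # (position, from_residue, to_residue)


@dataclass(frozen=True)
class EnumerationConfig:
    """Controls the substitution search: cap, mode, sample size, seed."""

    k_max: int = 5
    mode: str = "exhaustive"  # or "sampled"
    sample_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.mode not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "sampled" and self.sample_size < 1:
            raise ValueError("sample_size must be >= 1 in sampled mode")


@dataclass
class VariantSet:
    """Variants of one template plus their substitution records."""

    template: Peptide
    variants: list[Peptide] = field(default_factory=list)
    substitutions: list[tuple[Substitution, ...]] = field(default_factory=list)

    @property
    def template_id(self) -> str:
        return self.template.id

    def __len__(self) -> int:
        return len(self.variants)

    def to_fasta(self, path) -> None:
        """Write variants as FASTA; IDs encode parent and substitutions."""
        with open(path, "w") as fh:
            for p, subs in zip(self.variants, self.substitutions):
                tag = "_".join(f"{f}{pos}{t}" for pos, f, t in subs)
                fh.write(f">{self.template_id}_{tag}\n{p.sequence}\n")


def substitutable_choices(template: Peptide) -> dict[int, set[str]]:
    """Per-position admissible target residues: {K, R} minus the current one."""
    return {
        j: {"K", "R"} - {r} for j, r in enumerate(template.sequence)
    }


def count_variants(template: Peptide, k_max: int) -> int:
    """Closed-form size of the variant space for 1..k_max substitutions.

    Positions already K or R offer one choice, all others two; the count is
    Σ_k Σ_{a+b=k} C(m2, a)·2^a·C(m1, b) where m2/m1 are the numbers of
    two-/one-choice positions.
    """
    m1 = sum(1 for r in template.sequence if r in "KR")
    m2 = len(template.sequence) - m1
    total = 0
    for k in range(1, k_max + 1):
        for a in range(max(0, k - m1), min(k, m2) + 1):
            total += math.comb(m2, a) * 2**a * math.comb(m1, k - a)
    return total


def _variant_id(template: Peptide, subs: tuple[Substitution, ...]) -> str:
    tag = "_".join(f"{f}{pos}{t}" for pos, f, t in subs)
    return f"{template.id}_{tag}"


def _make_variant(template: Peptide, subs: tuple[Substitution, ...]) -> Peptide:
    chars = list(template.sequence)
    for pos, _from, to in subs:
        chars[pos] = to
    return Peptide(
        _variant_id(template, subs),
        "".join(chars),
        PeptideSource.VARIANT,
        parent_id=template.id,
    )


def enumerate_variants(template: Peptide, config: EnumerationConfig) -> VariantSet:
    """Enumerate (or sample) K/R substitution variants of a template.

    Exhaustive mode emits every distinct variant with 1..k_max substitutions
    and refuses with the predicted count when the space exceeds the safety
    bound.  Sampled mode draws ``sample_size`` distinct variants uniformly
    without replacement, bit-reproducibly from ``seed``.  Because no-op
    substitutions are excluded, distinct substitution records always yield
    distinct sequences; a dedupe pass guards the invariant regardless.
    """
    vs = VariantSet(template)
    if config.k_max == 0:
        warnings.warn("k_max=0: empty variant set", stacklevel=2)
        return vs

    total = count_variants(template, config.k_max)
    if config.mode == "exhaustive":
        if total > EXHAUSTIVE_SAFETY_BOUND:
            raise ValueError(
                f"exhaustive enumeration refused: predicted {total} variants "
                f"exceeds safety bound {EXHAUSTIVE_SAFETY_BOUND}"
            )
        _enumerate_exhaustive(template, config.k_max, vs)
    else:
        _enumerate_sampled(template, config, total, vs)
    return vs


def _enumerate_exhaustive(template: Peptide, k_max: int, vs: VariantSet) -> None:
    choices = substitutable_choices(template)
    seq = template.sequence
    seen: set[str] = set()
    positions = range(len(seq))
    for k in range(1, k_max + 1):
        for pos_set in itertools.combinations(positions, k):
            option_lists = [sorted(choices[j]) for j in pos_set]
            for targets in itertools.product(*option_lists):
                subs = tuple(
                    (j, seq[j], t) for j, t in zip(pos_set, targets)
                )
                variant = _make_variant(template, subs)
                if variant.sequence in seen:
                    continue  # unreachable under current semantics
                seen.add(variant.sequence)
                vs.variants.append(variant)
                vs.substitutions.append(subs)


def _enumerate_sampled(
    template: Peptide, config: EnumerationConfig, total: int, vs: VariantSet
) -> None:
    seq = template.sequence
    one_choice = [j for j, r in enumerate(seq) if r in "KR"]
    two_choice = [j for j, r in enumerate(seq) if r not in "KR"]
    m1, m2 = len(one_choice), len(two_choice)

    n_draw = config.sample_size
    if n_draw > total:
        warnings.warn(
            f"sample_size {n_draw} exceeds variant space {total}; "
            "returning the full space",
            stacklevel=2,
        )
        _enumerate_exhaustive(template, config.k_max, vs)
        return

    # Weight of a (a, b) stratum: a two-choice and b one-choice positions.
    strata: list[tuple[int, int]] = []
    weights: list[int] = []
    for k in range(1, config.k_max + 1):
        for a in range(max(0, k - m1), min(k, m2) + 1):
            strata.append((a, k - a))
            weights.append(math.comb(m2, a) * 2**a * math.comb(m1, k - a))
    prob = np.array(weights, dtype=float)
    prob /= prob.sum()

    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    while len(vs.variants) < n_draw:
        a, b = strata[rng.choice(len(strata), p=prob)]
        pos: list[int] = []
        if a:
            pos += list(rng.choice(m2, size=a, replace=False))
        subs_two = tuple(
            (two_choice[i], seq[two_choice[i]],
             sorted({"K", "R"} - {seq[two_choice[i]]})[rng.integers(2)])
            for i in pos
        )
        subs_one = ()
        if b:
            picks = rng.choice(m1, size=b, replace=False)
            subs_one = tuple(
                (one_choice[i], seq[one_choice[i]],
                 ("R" if seq[one_choice[i]] == "K" else "K"))
                for i in picks
            )
        subs = tuple(sorted(subs_two + subs_one))
        variant = _make_variant(template, subs)
        if variant.sequence in seen:
            continue
        seen.add(variant.sequence)
        vs.variants.append(variant)
        vs.substitutions.append(subs)


def apply_modification(
    template: Peptide, positions: list[int], residues: list[str]
) -> Peptide:
    """Apply explicit K/R substitutions at the given positions.

    The returned variant's Hamming distance to the template equals the number
    of positions whose residue actually changed (substituting K for K at a K
    position contributes 0).
    """
    if len(positions) != len(residues):
        raise ValueError("positions and residues must have the same length")
    chars = list(template.sequence)
    subs: list[Substitution] = []
    for pos, res in zip(positions, residues):
        if not 0 <= pos < len(chars):
            raise IndexError(f"position {pos} out of range for length {len(chars)}")
        if res not in ("K", "R"):
            raise ValueError(f"substitution residue must be K or R, got {res!r}")
        if chars[pos] != res:
            subs.append((pos, chars[pos], res))
        chars[pos] = res
    if not subs:
        return Peptide(
            f"{template.id}_id", "".join(chars), PeptideSource.VARIANT,
            parent_id=template.id,
        )
    return _make_variant(template, tuple(subs))
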