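# Methods

## Problem setting

Anticancer peptides (ACPs) act largely through electrostatic attraction to
the anionic outer leaflet of cancer-cell membranes (exposed
phosphatidylserine) followed by membrane disruption, which favours short,
cationic, amphipathic α-helices. `acpdesign` automates a design loop that
starts from the statistics of known ACPs and pushes candidates toward
higher cationicity while screening against predicted hemolytic risk.

## Consensus templates

Sequences are binned by exact length over a 15–20 residue window (inclusive
bounds, a practical synthesis range). Because every sequence in a bin
shares a length, "alignment" is plain columnar stacking — no gapped MSA is
performed or needed. Each bin yields a positional frequency matrix (PFM);
the consensus template takes the argmax residue per column, with ties broken
lexicographically by one-letter code so extraction is deterministic. The
per-column information content IC_j = log2(20) − H_j (Shannon entropy, bits,
0·log 0 ≡ 0) is reported for diagnostics only; no small-sample correction is
applied and IC never influences the consensus. Duplicate database sequences
are counted with multiplicity by default: redundancy in curated ACP
databases is part of the compositional signal.

## K/R variant space

From each template, candidates are generated by substituting 1..k_max
residues (default cap k_max = 5) with lysine or arginine. The target set at
position j is {K, R} minus the template residue, so K↔R swaps are admitted
but no-op substitutions are excluded; consequently every variant differs
from its template at 1..k_max positions, all of which hold K or R, and
distinct substitution records always produce distinct sequences. The space
size has the closed form Σ_k Σ_{|S|=k} Π_{j∈S} |choices_j|; for a K/R-free
19-mer at the default cap this is Σ_{k≤5} C(19,k)·2^k = 442 586.

Exhaustive enumeration is the default (worst case ≈ 6.8·10^5 for L = 20,
and a safety bound of 5·10^6 refuses pathological requests). Sampled mode
draws exactly uniformly over the space without replacement: a stratum
(a, b) — a two-choice and b one-choice positions — is selected with
probability proportional to C(m₂,a)·2^a·C(m₁,b), then positions and target
residues are drawn uniformly within the stratum, with rejection of repeated
sequences. Sampling is bit-reproducible from its seed.

## Descriptors

* **Molecular weight** — sum of average free-amino-acid masses minus one
  water (18.0153 Da) per peptide bond; free, unmodified termini are assumed
  throughout (no amidation/acetylation).
* **Net charge** — two modes. *Integer*: +1 per K/R and the free
  N-terminus, −1 per D/E and the free C-terminus, histidine neutral — the
  convention under which designed ACPs are quoted with charges like +7 or
  +9. *Henderson–Hasselbalch* (default, pH 7.0): each ionizable group
  titrated with the EMBOSS pKa set (C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
  R 12.5, Y 10.1; termini 8.6/3.6); basic groups contribute
  10^pKa/(10^pKa+10^pH), acidic groups −10^pH/(10^pKa+10^pH). HH charge is
  strictly decreasing in pH by construction.
* **Hydrophobicity** — the Eisenberg consensus scale (the scale used by the
  Heliquest web tool), shipped as a versioned TSV and pluggable via
  `ScaleTable`. ⟨H⟩ is the arithmetic per-residue mean.
* **Hydrophobic moment** — μH = (1/N)·|Σₙ Hₙ e^{inδ}| with δ = 100° per
  residue (ideal α-helix; exposed via `HelixGeometry`). μH is non-negative
  and bounded by max|H|; an 18-mer homopolymer vanishes exactly because 18
  steps of 100° cover all multiples of 20°.
* **Face segregation** — wheel angles of the hydrophobic residues
  (A, C, F, I, L, M, V, W) are scanned against all 360 half-plane arcs at 1°
  resolution; the statistic is the maximum fraction capturable by one arc
  (the value, not the arc, is returned; ties are immaterial). A peptide
  with no hydrophobic residues returns 0 by convention; lengths < 3 are
  rejected.
* **Solubility** — a labelled heuristic, not a physical model: "good" iff
  the hydrophilic fraction (D, E, K, R, H, N, Q, S, T) ≥ 0.25 and the
  integer-mode |charge| ≥ 1. Published calculators do not document their
  rule, so an explicit one is preferable to an opaque imitation.

## Activity scoring

The predictors used in practice for anticancer (mACPpred, ACPred, ENNACT),
cell-penetration (CellPPD, BchemRF-CPPred, MLCPP), and hemolysis (HAPPENN,
DBAASP, HemoPI) screening are web services with unpublished weights, so
they are not re-implemented. Instead each category has a *surrogate*: a
logistic squash of a linear combination of interpretable features, each
centred on a policy midpoint (defaults: charge +5, μH 0.3, K/R fraction
0.3, ⟨H⟩ 0.2) so that a peptide sitting exactly at the midpoints scores
0.5.

* anticancer: integer charge, μH, K/R fraction, minus a penalty per residue
  outside the 15–20 window — monotone non-decreasing in charge and μH;
* cell-penetration: integer charge, R fraction, face segregation — monotone
  in charge;
* hemolysis (a **risk**, higher = worse): ⟨H⟩, μH, hydrophobic fraction —
  monotone in ⟨H⟩.

Slopes and midpoints are tunable policy data, not claims about any
predictor. Real predictor outputs can be imported from a delimited table
(sequence column + per-tool columns, optional declared min–max ranges for
rescaling); multiple tools per category are combined by unweighted mean,
and imported entries replace the surrogates for matching sequences.

The overall score is `w_ac·AC + w_cpp·CPP + w_hem·(1 − Hem)` with weights
normalized to sum to 1 (default equal thirds). Ranking is total and
deterministic: overall descending, ties by lower hemolysis, then by
sequence. Because substitutions only introduce K/R and the scorers are
charge-monotone, the top candidate's integer charge never falls below its
template's — the mechanism by which the pipeline raises cationicity.

## Synthetic corpus generator

`PlantedModel` emulates a curated ACP database: for each length a planted
consensus is fixed (drawn from a K/R- and hydrophobe-enriched residue pool
when not supplied), and each position of each synthetic sequence emits the
planted residue with probability p (default 0.6) or a background residue —
uniform over the other 19 with K and R up-weighted ×3, mirroring ACP
composition bias. Defaults are 200 sequences per length. The model is
positional-i.i.d. by design: it makes consensus recovery a well-posed,
analyzable test (planted frequency is exactly p, so binomial concentration
applies), but it does **not** reproduce real databases' activity
annotations, phylogenetic correlation between sequences, or within-sequence
residue dependencies — a green recovery test certifies the counting and
argmax machinery, not biological realism. The score-table generator couples
synthetic tool outputs monotonically to charge (activity/CPP columns) or
hydrophobicity (hemolysis columns) plus seeded Gaussian noise (σ = 0.05),
clipped to [0, 1].

## Determinism and numerics

All pipeline randomness descends from the single run seed: template i's
sampling stream uses `SeedSequence(seed, spawn_key=(i,))`. Report artifacts
(TSV, JSON, FASTA) contain the config echo, version, and stage counts but
no wall-clock state, so identical config + seed reproduces them byte for
byte; timestamps appear only in logs. Arc scanning uses 1° resolution;
exact score ties are resolved by the documented (hemolysis, sequence)
tie-break with a stable sort. Zero-hydrophobe peptides define segregation
0; k_max = 0 yields an empty variant set with a warning rather than an
error.

## Limitations

* Surrogate scores are transparent monotone proxies, not trained
  classifiers; absolute values are only meaningful relative to the policy.
* No secondary/tertiary-structure prediction: helicity is assumed, not
  predicted, and the wheel analysis presumes an ideal helix.
* Integer charge ignores pH; HH mode assumes free termini and standard
  pKa values (no environment shifts).
* Only K/R point substitutions are explored — no deletions, insertions,
  other residues, or D-amino acids.
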