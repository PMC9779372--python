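# acpdesign

De novo design of cationic amphipathic anticancer peptides (ACPs), as a
library and CLI.

Known ACPs are short (here 15–20 residues), cationic, and amphipathic:
their positive charge targets the anionic outer membranes of cancer cells,
and the segregation of hydrophobic and hydrophilic residues onto opposite
helical faces drives membrane disruption. `acpdesign` automates a rational
design loop built on those observations:

1. **Templates** — load a database of known ACP sequences, bin by length
   (15–20 AA), stack each bin into a positional frequency matrix, and take
   the most frequent residue at every position as the per-length consensus
   template (six templates for a full-window corpus).
2. **Variants** — enumerate (or uniformly sample) all candidates obtained by
   substituting up to five template residues with lysine (K) or arginine
   (R), raising cationicity.
3. **Characterization** — for every candidate: molecular weight, net charge
   (integer counting or Henderson–Hasselbalch titration with the EMBOSS pKa
   set), mean hydrophobicity ⟨H⟩ and the Eisenberg hydrophobic moment

   μH = (1/N) · | Σₙ Hₙ e^(i n δ) |,  δ = 100°/residue,

   helical-wheel projection, hydrophobic-face segregation, and a documented
   water-solubility heuristic.
4. **Scoring & selection** — transparent monotone surrogates score each
   candidate for anticancer, cell-penetrating, and hemolytic potential
   (outputs of real predictor tools can be imported from tables instead);
   candidates are ranked by
   `overall = w₁·anticancer + w₂·cell_penetration + w₃·(1 − hemolysis)`.

A seeded synthetic-corpus generator (`acpdesign.synth`) plants a known
consensus in every length bin so the whole pipeline is testable offline.

## Worked example

Generate a synthetic 1200-sequence corpus and run the pipeline:

```python
from acpdesign import PlantedModel, generate_mock_db
generate_mock_db(PlantedModel(n_per_length=200, seed=7), fasta_path="acp_db.fasta")
```

```sh
acpdesign design --db acp_db.fasta --mode sampled --sample-size 500 \
    --seed 7 --top 3 --out demo_out
```

The run log reports each stage (1200 records → 6 templates → 3000 variants
→ top 3), and `demo_out/report.tsv` contains:

```text
rank  sequence             net_charge_integer  hydrophobic_moment  overall
1     KRAVRRKRIKAGRRFRASR  11                  0.367               0.982
2     KRARRRKLIKAGRRFLRSR  11                  0.338               0.982
3     KRAVRRVRRKAGRRFLARR  11                  0.401               0.982
```

Each winner is a 19-mer template with five K/R substitutions (encoded in its
FASTA ID, e.g. `T19_S4R_V6K_L7R_A12R_L15R`), a net charge of +11, and a
non-trivial hydrophobic moment — exactly the cationic, amphipathic profile
the screen is built to favour. Single-peptide characterization:

```sh
$ acpdesign props KRWWKWIRRKK
        ...
      molecular_weight: 1671.07      # Da, average masses, free termini
            net_charge: 6.9753       # Henderson–Hasselbalch at pH 7
    net_charge_integer: 7            # +1 per K/R + N-term, −1 per D/E + C-term
   mean_hydrophobicity: -0.8891      # Eisenberg consensus scale
    hydrophobic_moment: 0.6887       # strongly amphipathic
      face_segregation: 1.0000       # all hydrophobics on one helical face
            solubility: good         # heuristic
```

`acpdesign wheel SEQ [--svg wheel.svg]` prints the helical-wheel table;
`templates`, `enumerate`, and `score` expose the individual stages.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a seeded synthetic corpus and runs the complete pipeline
(templates → variants → scoring → ranking) end to end, writing its results
object to the given path.
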