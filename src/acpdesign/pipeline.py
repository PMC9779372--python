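"""End-to-end design pipeline orchestration.

``run_design`` wires the stages together: load the sequence database, filter
to the length window, derive per-length consensus templates, enumerate K/R
substitution variants per template, characterize and score every candidate,
and rank them into a single report.  The run is fully deterministic under a
fixed configuration: all randomness descends from the single config seed via
``numpy.random.SeedSequence`` spawning (one child stream per template, keyed
by template index), and report files contain no wall-clock state, so a fixed
seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .db import (
    ConsensusTemplate,
    derive_templates,
    filter_by_length,
    load_database,
    templates_to_fasta,
)
from .peptide import HelixGeometry, ScaleTable, default_scale
from .scoring import ScorePolicy, import_external_scores, rank_candidates
from .variants import EnumerationConfig, VariantSet, enumerate_variants

__all__ = ["RunConfig", "CandidateReport", "run_design"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration for one design run.

    Mirrors the CLI flags one-to-one and round-trips through YAML/JSON, so
    the config echo embedded in a report can reproduce the run exactly.
    """

    db_path: str
    db_format: str = "fasta"
    min_len: int = 15
    max_len: int = 20
    k_max: int = 5
    mode: str = "exhaustive"
    sample_size: int = 1000
    seed: int = 0
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    scores_table: str | None = None
    top_n: int = 50
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.mode not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown enumeration mode {self.mode!r}")
        object.__setattr__(self, "weights", tuple(self.weights))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "weights" in d:
            d["weights"] = tuple(d["weights"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CandidateReport:
    """Ranked candidate table plus run metadata.

    ``table`` rows are sorted by overall score descending (ties: lower
    hemolysis, then sequence) with contiguous ranks from 1.  ``metadata``
    echoes the config, the package version, and per-stage record counts —
    but never wall-clock timestamps, so reports are reproducible byte for
    byte.
    """

    table: pd.DataFrame
    metadata: dict
    templates: list[ConsensusTemplate] = field(default_factory=list)
    variant_sets: list[VariantSet] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "candidates": self.table.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write report TSV + JSON, templates FASTA, and variants FASTA."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report_tsv": out / "report.tsv",
            "report_json": out / "report.json",
            "templates_fasta": out / "templates.fasta",
            "variants_fasta": out / "variants.fasta",
        }
        self.table.to_csv(paths["report_tsv"], sep="\t", index=False)
        paths["report_json"].write_text(self.to_json() + "\n")
        templates_to_fasta(self.templates, paths["templates_fasta"])
        with open(paths["variants_fasta"], "w") as fh:
            for vs in self.variant_sets:
                for pep, subs in zip(vs.variants, vs.substitutions):
                    tag = "_".join(f"{f}{p}{t}" for p, f, t in subs)
                    fh.write(f">{vs.template_id}_{tag}\n{pep.sequence}\n")
        return paths


def _template_seed(base_seed: int, template_index: int) -> int:
    """Derive the per-template sampling seed from the run seed.

    Spawn-key derivation keeps streams independent across templates while
    remaining a pure function of (base_seed, template_index).
    """
    ss = np.random.SeedSequence(base_seed, spawn_key=(template_index,))
    return int(ss.generate_state(1)[0] % 2**31)


def run_design(
    config: RunConfig,
    scale: ScaleTable | None = None,
    geometry: HelixGeometry | None = None,
) -> CandidateReport:
    """Execute the full design pipeline and return the ranked report.

    Stages: load → length filter → consensus templates → per-template K/R
    variant enumeration → descriptor + activity scoring → global ranking →
    top-N selection.  Any stage error aborts the run (no partial outputs);
    every stage logs its record count.
    """
    scale = scale or default_scale()
    geometry = geometry or HelixGeometry()
    policy = ScorePolicy(
        weights=config.weights, min_len=config.min_len, max_len=config.max_len
    )

    db = load_database(config.db_path, format=config.db_format)
    logger.info("stage load: %d records", len(db))

    db = filter_by_length(db, config.min_len, config.max_len)
    logger.info("stage filter: %d records in [%d, %d]",
                len(db), config.min_len, config.max_len)

    templates = derive_templates(db, config.min_len, config.max_len)
    if not templates:
        raise RuntimeError("stage templates: no consensus templates derivable")
    logger.info("stage templates: %d consensus templates", len(templates))

    external = None
    if config.scores_table:
        external = import_external_scores(config.scores_table)
        logger.info("stage scores: imported %d external entries", len(external))

    variant_sets: list[VariantSet] = []
    frames: list[pd.DataFrame] = []
    n_variants = 0
    for i, tmpl in enumerate(templates):
        enum_cfg = EnumerationConfig(
            k_max=config.k_max,
            mode=config.mode,
            sample_size=config.sample_size,
            seed=_template_seed(config.seed, i),
        )
        vs = enumerate_variants(tmpl.peptide, enum_cfg)
        n_variants += len(vs)
        variant_sets.append(vs)
        if len(vs):
            frames.append(
                rank_candidates(vs, policy, scale, geometry, external)
            )
    logger.info("stage enumerate: %d variants across %d templates",
                n_variants, len(templates))

    if not frames:
        raise RuntimeError("stage score: no variants to score")
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["overall", "hemolysis", "sequence"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = table.index + 1

    if config.top_n > len(table):
        warnings.warn(
            f"top_n {config.top_n} exceeds candidate count {len(table)}; "
            "returning the full ranked list",
            stacklevel=2,
        )
    top = table.head(config.top_n).reset_index(drop=True)
    logger.info("stage rank: %d candidates scored, reporting top %d",
                len(table), len(top))

    metadata = {
        "config": config.to_dict(),
        "version": __version__,
        "seed": config.seed,
        "n_db_records": len(db),
        "n_templates": len(templates),
        "template_sequences": {
            t.length: t.peptide.sequence for t in templates
        },
        "n_variants": n_variants,
        "n_scored": int(len(table)),
        "n_reported": int(len(top)),
    }
    report = CandidateReport(top, metadata, templates, variant_sets)
    if config.out_dir:
        report.write(config.out_dir)
    return report
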