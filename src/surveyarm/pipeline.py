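"""End-to-end pipeline orchestration and the run manifest.

score -> recode -> encode -> mine -> rules -> cohort compare, from a
survey CSV, a scored CSV, or a basket file, writing per-cohort rule
files, a comparison report, and a JSON manifest recording inputs,
configuration, seed, and per-stage record counts.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .basket_encoder import (
    DEFAULT_TAGS,
    TransactionDB,
    encode_cohort,
    read_baskets,
    write_baskets,
)
from .cohort_analysis import (
    BOTH,
    build_report,
    compare_cohorts,
    mine_by_cohort,
)
from .rule_engine import AssociationRule, MinerConfig
from .survey_model import (
    DEFAULT_SUBSCALES,
    SubscaleDefinition,
    ValidationError,
    read_scores_csv,
    read_survey_csv,
    score_records,
    write_scores_csv,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_rules_csv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    miner: MinerConfig = MinerConfig()
    mode: str = "combined"
    tags: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_TAGS))
    subscales: tuple[SubscaleDefinition, ...] = DEFAULT_SUBSCALES
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "miner": asdict(self.miner),
                "mode": self.mode,
                "tags": dict(self.tags),
                "subscales": [d.domain_code for d in self.subscales],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance for one pipeline run."""

    input_path: str
    output_paths: dict[str, str]
    config: dict
    config_hash: str
    seed: int
    version: str
    stage_counts: dict[str, int]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def write_rules_csv(
    rules: Sequence[AssociationRule],
    decoded: Sequence[str],
    path: str | Path,
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["antecedent", "consequent", "support", "confidence", "lift", "interpretation"]
        )
        for rule, text in zip(rules, decoded):
            writer.writerow(
                [
                    " ".join(sorted(rule.antecedent)),
                    " ".join(sorted(rule.consequent)),
                    f"{rule.support:.6f}",
                    f"{rule.confidence:.6f}",
                    f"{rule.lift:.6f}",
                    text,
                ]
            )


def _load_transactions(
    input_path: Path, config: PipelineConfig, outdir: Path, counts: dict[str, int]
) -> tuple[TransactionDB, dict[str, str]]:
    outputs: dict[str, str] = {}
    if input_path.suffix.lower() == ".csv":
        with input_path.open() as fh:
            header = fh.readline().strip().split(",")
        domain_cols = {d.domain_code for d in config.subscales}
        if domain_cols <= set(header):
            vectors = read_scores_csv(input_path, config.subscales)
            counts["scored"] = len(vectors)
        else:
            records = read_survey_csv(input_path, config.subscales)
            counts["survey_rows"] = len(records)
            vectors = score_records(records, config.subscales)
            counts["scored"] = len(vectors)
            scored_path = outdir / "scored.csv"
            write_scores_csv(vectors, scored_path, config.subscales)
            outputs["scored"] = str(scored_path)
        db = encode_cohort(vectors, config.subscales, config.tags)
    else:
        db = read_baskets(input_path, config.subscales, config.tags)
    counts["transactions"] = db.n
    counts["vocabulary"] = len(db.vocabulary)
    basket_path = outdir / "baskets.txt"
    write_baskets(db, basket_path)
    outputs["baskets"] = str(basket_path)
    return db, outputs


def run_pipeline(
    input_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> RunManifest:
    """Run the full pipeline and write all outputs plus a manifest.

    Idempotent given the same inputs and seed; any stage failure raises
    ValidationError with stage context.
    """
    input_path = Path(input_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    logger.info(
        "thresholds in use: minsup=%s minconf=%s minlift=%s (mode=%s)",
        config.miner.minsup, config.miner.minconf, config.miner.minlift, config.mode,
    )

    db, outputs = _load_transactions(input_path, config, outdir, counts)

    by_cohort = mine_by_cohort(db, config.miner, config.tags, config.mode)
    provenance = {
        "input": str(input_path),
        "seed": config.seed,
        "config_hash": config.digest(),
    }
    reports = {}
    for cohort, rules in by_cohort.items():
        report = build_report(
            cohort, rules, config.miner, config.subscales, config.tags, provenance
        )
        reports[cohort] = report
        counts[f"rules_{cohort}"] = report.n_rules
        rules_path = outdir / f"rules_{cohort}.csv"
        write_rules_csv(report.rules, report.decoded, rules_path)
        outputs[f"rules_{cohort}"] = str(rules_path)

    cohorts = [c for c in reports if c != BOTH]
    if len(cohorts) == 2:
        comparison = compare_cohorts(reports[cohorts[0]], reports[cohorts[1]])
        comparison["n_rules_both"] = reports[BOTH].n_rules if BOTH in reports else 0
        cmp_path = outdir / "comparison.json"
        cmp_path.write_text(json.dumps(comparison, indent=2, default=str) + "\n")
        outputs["comparison"] = str(cmp_path)

    manifest = RunManifest(
        input_path=str(input_path),
        output_paths=outputs,
        config={
            "miner": asdict(config.miner),
            "mode": config.mode,
            "tags": dict(config.tags),
        },
        config_hash=config.digest(),
        seed=config.seed,
        version=__version__,
        stage_counts=counts,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
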