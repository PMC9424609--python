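"""End-to-end discovery and validation runs driven by a manifest.

``run_discover`` reads only the training cohorts, runs the meta-analysis,
filters candidates, performs the forward search and writes every artifact
(meta table, signature JSON, per-cohort score TSVs, ROC/AUC report, run
log). ``run_validate`` scores validation cohorts with a frozen signature and
never re-fits anything. The strict separation means validation files may be
absent entirely at discovery time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

from . import diagnostics, meta_analysis, signature_search
from .io_cohorts import Manifest, intersect_genes
from .signature_search import Signature

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunArtifacts:
    out_dir: Path
    meta_table: Path | None = None
    flagged_table: Path | None = None
    signature: Path | None = None
    score_tables: dict[str, Path] = field(default_factory=dict)
    roc_report: Path | None = None
    run_log: Path | None = None
    summary: dict = field(default_factory=dict)


def _package_version() -> str:
    try:
        return metadata.version("metasig")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _start_log(out_dir: Path, manifest: Manifest, command: str) -> Path:
    log_path = out_dir / "run.log"
    cfg = manifest.options
    with open(log_path, "w") as fh:
        fh.write(f"metasig {_package_version()} :: {command}\n")
        fh.write("config:\n")
        for key, value in vars(cfg).items():
            fh.write(f"  {key}: {value}\n")
        fh.write("cohorts:\n")
        for entry in manifest.cohorts:
            fh.write(f"  {entry}\n")
    return log_path


def _score_and_report(
    cohorts,
    signature: Signature,
    manifest: Manifest,
    out_dir: Path,
    artifacts: RunArtifacts,
    report_name: str,
) -> None:
    cfg = manifest.options
    scored = []
    for cohort in cohorts:
        sc = signature_search.meta_score(cohort, signature)
        scored.append(sc)
        path = out_dir / f"scores_{cohort.id}.tsv"
        signature_search.write_scores(sc, cohort.sample_ids, path)
        artifacts.score_tables[cohort.id] = path
    per_cohort = [
        diagnostics.roc_result(s, cfg.auc_ci_method, cfg.bootstrap_reps, cfg.rng_seed)
        for s in scored
    ]
    summary = diagnostics.summary_auc(
        scored, cfg.auc_ci_method, cfg.bootstrap_reps, cfg.rng_seed
    )
    report = {
        "cohorts": [r.to_dict() for r in per_cohort],
        "summary": summary.to_dict(),
    }
    report_path = out_dir / report_name
    report_path.write_text(json.dumps(report, indent=2) + "\n")
    artifacts.roc_report = report_path
    artifacts.summary = report


def run_discover(manifest: Manifest, out_dir: str | Path) -> RunArtifacts:
    """Discovery: intersect -> effects -> meta -> filter -> forward search."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = RunArtifacts(out_dir=out_dir)
    artifacts.run_log = _start_log(out_dir, manifest, "discover")
    cfg = manifest.options

    try:
        cohorts = manifest.load_cohorts(role="training")
    except Exception as exc:
        raise PipelineError(f"stage load-training: {exc}") from exc
    if not cohorts:
        raise PipelineError("stage load-training: no training cohorts in manifest")

    try:
        cohorts = intersect_genes(cohorts)
        results = meta_analysis.run_meta(cohorts, cfg)
    except Exception as exc:
        raise PipelineError(f"stage meta-analysis: {exc}") from exc

    artifacts.meta_table = out_dir / "meta_table.tsv"
    artifacts.flagged_table = out_dir / "flagged_genes.tsv"
    meta_analysis.write_meta(results, artifacts.meta_table, artifacts.flagged_table)

    candidates = meta_analysis.flagged(results)
    if not candidates:
        raise PipelineError(
            "stage forward-search: no candidates (no gene passed the ES/FDR filter)"
        )
    try:
        signature = signature_search.forward_search(
            candidates, cohorts, cfg.forward_search_min_improvement
        )
    except Exception as exc:
        raise PipelineError(f"stage forward-search: {exc}") from exc

    artifacts.signature = out_dir / "signature.json"
    signature.to_json(artifacts.signature)

    try:
        _score_and_report(
            cohorts, signature, manifest, out_dir, artifacts, "roc_training.json"
        )
    except Exception as exc:
        raise PipelineError(f"stage scoring: {exc}") from exc
    logger.info(
        "discover: signature %s, training summary AUC %.4f",
        sorted(signature.genes),
        artifacts.summary["summary"]["auc"],
    )
    return artifacts


def run_validate(
    manifest: Manifest, signature_path: str | Path, out_dir: str | Path
) -> RunArtifacts:
    """Validation: score held-out cohorts with a frozen signature."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = RunArtifacts(out_dir=out_dir)
    artifacts.run_log = _start_log(out_dir, manifest, "validate")
    signature = Signature.from_json(signature_path)
    artifacts.signature = Path(signature_path)

    try:
        cohorts = manifest.load_cohorts(role="validation")
    except Exception as exc:
        raise PipelineError(f"stage load-validation: {exc}") from exc
    if not cohorts:
        raise PipelineError("stage load-validation: no validation cohorts in manifest")
    try:
        _score_and_report(
            cohorts, signature, manifest, out_dir, artifacts, "roc_validation.json"
        )
    except Exception as exc:
        raise PipelineError(f"stage scoring: {exc}") from exc
    logger.info(
        "validate: summary AUC %.4f", artifacts.summary["summary"]["auc"]
    )
    return artifacts
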