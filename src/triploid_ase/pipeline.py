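"""End-to-end driver: DEG gate -> ASE calls -> summaries -> enrichment.

``run_pipeline`` sequences the stages on validated inputs and writes every
output table plus a manifest recording the configuration, seed and input
checksums, so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import ase_calling, deg_calling, enrichment, family_summary
from .core_io import (
    AllelePairSet,
    AnnotationMap,
    ExpressionMatrix,
    PipelineConfig,
    file_sha256,
)
from .errors import TriploidASEError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class StageError(TriploidASEError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix,
    pairs: AllelePairSet,
    annotations: AnnotationMap | None = None,
    out_dir: str | Path | None = None,
    cultivar: str | None = None,
    input_paths: dict[str, str] | None = None,
) -> dict:
    """Run the full analysis and (optionally) write all outputs.

    Returns a bundle dict with keys ``deg`` (DEGAlleleSet), ``ase_calls``,
    ``genome_summary``, ``family_tables``, ``enrichment`` and ``manifest``.
    """
    model = config.ploidy_model()
    logger.info(
        "ASE thresholds: dosage ratio %.3g, upper %.3g, lower %.3g; "
        "DEG gate: FC >= %.3g at FDR < %.3g vs %d DPH",
        model.dosage_ratio, model.upper_threshold, model.lower_threshold,
        config.deg_fc_threshold, config.deg_alpha, config.baseline_stage_dph,
    )

    def _stage(name, fn):
        try:
            return fn()
        except TriploidASEError as exc:
            raise StageError(name, exc) from exc

    deg = _stage("deg_calling", lambda: deg_calling.call_deg_alleles(
        expression, pairs, config, cultivar=cultivar))
    calls = _stage("ase_calling", lambda: ase_calling.classify_all(
        expression, deg, model,
        min_expression=config.min_expression_rpkm,
        baseline_stage_dph=config.baseline_stage_dph,
        cultivar=cultivar))
    summary = _stage("genome_summary", lambda: ase_calling.genome_wide_summary(
        calls, n_deg_alleles=len(deg)))

    family_tables = pd.DataFrame()
    enrich_results = {}
    if annotations is not None:
        stages = sorted(calls["stage_dph"].unique())
        fam = [family_summary.family_table(calls, annotations, s) for s in stages]
        family_tables = pd.concat(fam, ignore_index=True) if fam else pd.DataFrame()

        annotated = set(annotations.entries)
        universe = set(deg.pair_ids) & annotated
        for s in stages:
            stage_calls = calls[calls["stage_dph"] == s]
            ase_pairs = set(
                stage_calls.loc[
                    stage_calls["call"].isin(
                        [ase_calling.ASEClass.B_DOMINANT, ase_calling.ASEClass.A_DOMINANT]
                    ),
                    "pair_id",
                ]
            )
            selected = ase_pairs & universe
            if universe:
                enrich_results[s] = enrichment.hypergeom_enrich(
                    selected, universe, annotations)

    manifest = {
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "inputs": {
            name: file_sha256(p) for name, p in (input_paths or {}).items()
        },
        "thresholds": {
            "dosage_ratio": model.dosage_ratio,
            "upper": model.upper_threshold,
            "lower": model.lower_threshold,
        },
        "n_pairs_input": len(pairs),
        "n_deg_alleles": len(deg),
    }

    bundle = {
        "deg": deg,
        "ase_calls": calls,
        "genome_summary": summary,
        "family_tables": family_tables,
        "enrichment": enrich_results,
        "manifest": manifest,
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    deg = bundle["deg"]
    deg.records.to_csv(out / "deg_records.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
    deg.pair_members.to_csv(out / "deg_pairs.tsv", sep="\t", index=False)
    bundle["ase_calls"].to_csv(out / "ase_calls.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)
    bundle["genome_summary"].to_csv(out / "genome_summary.tsv", sep="\t",
                                    index=False, float_format=_FLOAT_FMT)
    if len(bundle["family_tables"]):
        bundle["family_tables"].to_csv(out / "family_summary.tsv", sep="\t",
                                       index=False, float_format=_FLOAT_FMT)
    for stage, res in bundle["enrichment"].items():
        res.to_csv(out / f"enrichment_{stage}dph.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    (out / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, sort_keys=True) + "\n"
    )
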