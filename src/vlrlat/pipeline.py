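"""End-to-end pipeline: curate, classify, discover, reclassify, simulate,
recommend, and write publication-style report tables.

All stages are composed in protocol order. Output tables have fixed column
schemas and deterministic row order; every output directory carries exactly
one run manifest with input checksums and the configuration echo.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pandas as pd

from . import __version__
from .battery import recommend_task_order, simulate_task_subsets, subsets_frame
from .concordance import ExpansionReport, indicator_frame, run_vlr_expansion
from .laterality import LateralityResult
from .model import AnalysisConfig, Cohort, CurationReport, Dominance, curate_cohort

logger = logging.getLogger("vlrlat")


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _li_fields(li: Fraction | None) -> dict:
    if li is None:
        return {"li": None, "li_num": None, "li_den": None}
    return {
        "li": f"{float(li):.4f}",
        "li_num": li.numerator,
        "li_den": li.denominator,
    }


def classification_frame(results: dict[str, LateralityResult]) -> pd.DataFrame:
    rows = []
    for pid in sorted(results):
        res = results[pid]
        rows.append(
            {
                "patient_id": pid,
                "n_left": res.counts.left,
                "n_right": res.counts.right,
                **_li_fields(res.li),
                "category": res.category.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "n_left", "n_right", "li", "li_num", "li_den", "category"],
    )


@dataclass
class PipelineResult:
    curated: Cohort
    curation: CurationReport
    expansion: ExpansionReport
    subsets: list
    recommendation: object
    summary: dict


def run_full_pipeline(
    cohort: Cohort,
    config: AnalysisConfig | None = None,
    out_dir: str | os.PathLike | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Execute all stages on a raw cohort; write report tables when
    ``out_dir`` is given."""
    config = config or AnalysisConfig()
    baseline = config.resolve_vlr_set()

    logger.info("stage curate: %d sessions in", len(cohort))
    curated, curation = curate_cohort(cohort)
    logger.info(
        "stage curate: kept %d/%d patients, %d/%d sessions",
        curation.n_patients_out,
        curation.n_patients_in,
        curation.n_sessions_out,
        curation.n_sessions_in,
    )

    expansion = run_vlr_expansion(curated, baseline, config)
    logger.info(
        "stage discover: %d VLR cells; classifiable %d (baseline) -> %d (discovered)",
        len(expansion.discovery.vlr),
        expansion.n_classifiable_old,
        expansion.n_classifiable_new,
    )

    discovered = expansion.discovery.vlr
    subsets = simulate_task_subsets(curated, discovered, config)
    recommendation = recommend_task_order(subsets)
    logger.info(
        "stage order: recommended %s",
        " -> ".join(t.value for t in recommendation.order),
    )

    n_analyzed = len(expansion.patients)
    cat_counts = {
        d.value: sum(p.cat_new is d for p in expansion.patients) for d in Dominance
    }
    full = next(s for s in subsets if len(s.subset) == 4)
    summary = {
        "n_patients_analyzed": n_analyzed,
        "n_classifiable_baseline": expansion.n_classifiable_old,
        "n_classifiable_discovered": expansion.n_classifiable_new,
        "n_newly_classifiable": len(expansion.newly_classifiable),
        "newly_classifiable": list(expansion.newly_classifiable),
        "n_discovered_vlr": len(discovered),
        "n_concordant": expansion.table.n_concordant,
        "n_discordant": expansion.table.n_discordant,
        "category_counts_discovered": cat_counts,
        "delta_li": expansion.delta_li_summary(),
        "n_reference_classified": full.n_correct
        + full.n_incorrect
        + full.n_unclassifiable,
        "recommended_order": [t.value for t in recommendation.order],
        "curation": curation.to_dict(),
    }
    if n_analyzed == 0:
        summary["note"] = "0 patients analyzable"

    result = PipelineResult(curated, curation, expansion, subsets, recommendation, summary)
    if out_dir is not None:
        write_report_bundle(result, cohort, config, Path(out_dir), seed=seed)
    return result


def write_report_bundle(
    result: PipelineResult,
    raw_cohort: Cohort,
    config: AnalysisConfig,
    out_dir: Path,
    seed: int | None = None,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    kw = dict(sep="\t", index=False)
    result.expansion.table.to_frame().to_csv(out_dir / "concordance.tsv", **kw)
    result.expansion.discovery.audit_frame().to_csv(out_dir / "vlr_audit.tsv", **kw)
    result.expansion.to_frame().to_csv(out_dir / "li_comparison.tsv", **kw)
    subsets_frame(result.subsets).to_csv(out_dir / "subsets.tsv", **kw)
    indicator_frame(result.curated, result.expansion.discovery.vlr).to_csv(
        out_dir / "indicators.tsv", **kw
    )
    with open(out_dir / "order.json", "w", encoding="utf-8") as fh:
        json.dump(result.recommendation.to_dict(), fh, indent=2)
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2)
    write_manifest(
        out_dir,
        inputs={},
        config=config,
        seed=seed,
        extra={"n_raw_sessions": len(raw_cohort)},
    )


def write_manifest(
    out_dir: Path,
    inputs: dict[str, str],
    config: AnalysisConfig | None,
    seed: int | None = None,
    extra: dict | None = None,
) -> dict:
    """Write the run manifest: input checksums, config echo, version, time."""
    manifest = {
        "package": "vlrlat",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "inputs": {
            str(p): _sha256(p) for p in inputs.values() if p and os.path.exists(p)
        },
        "config": None
        if config is None
        else {
            "min_vlr_activations": config.min_vlr_activations,
            "min_vlr_sessions": config.min_vlr_sessions,
            "li_inner": str(config.li_inner),
            "vlr_set": config.vlr_set,
        },
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
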