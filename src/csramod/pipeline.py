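"""End-to-end analysis pipeline: sites -> ensemble -> regulation -> pockets.

Per-record failures are isolated (logged and reported in a failure
manifest); the cohort stage aggregates contingency counts and SD-overlap
statistics.  Reports embed the configuration hash and the folding-engine
identifier, and identical (input, config) runs produce identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

from .config import ModelConfig
from .ensemble import build_ensemble, ensemble_summary
from .energy import scan_sites
from .folding import FoldCache, FoldingEngine, ViennaEngine
from .pockets import (
    build_pockets,
    classify_conformations,
    flag_flexible_pockets,
    sd_overlap_report,
)
from .records import MRNARecord
from .translation import regulate_record

__all__ = ["run_pipeline", "default_engine", "report_to_json"]

log = logging.getLogger(__name__)


def default_engine(config: ModelConfig | None = None) -> ViennaEngine:
    config = config or ModelConfig()
    return ViennaEngine(
        temperature=config.engine_temperature,
        dangles=config.engine_dangles,
        parameters=config.engine_parameters,
    )


def _site_row(site) -> dict:
    return dataclasses.asdict(site)


def _conformation_row(conf) -> dict:
    return {
        "site1_start": conf.site1.start,
        "site1_seq": conf.site1.sequence,
        "site2_start": conf.site2.start,
        "site2_seq": conf.site2.sequence,
        "d": conf.d,
        "dG_site1": conf.site1.dG_site,
        "dG_site2": conf.site2.dG_site,
        "dG_coop": conf.dG_coop,
        "ddG_unfold": conf.ddG_unfold,
        "dG_total": conf.dG_total,
        "boltzmann_p": conf.boltzmann_p,
        "scaled_p": conf.scaled_p,
    }


def run_pipeline(
    records: list[MRNARecord],
    config: ModelConfig | None = None,
    engine: FoldingEngine | None = None,
) -> dict:
    """Run the full model over a cohort of records.

    Returns a JSON-serializable report: per-record sites, ensemble summary,
    top-K conformations, regulation call, and pockets; cohort-level
    contingency counts and SD-overlap percentages; and a failure manifest.
    """
    config = config or ModelConfig()
    engine = engine or default_engine(config)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "engine": engine.identifier,
        "records": {},
        "failures": {},
    }
    if not records:
        log.warning("empty record list: nothing to analyze")
    ensembles = []
    analyzed_records = []
    for rec in records:
        t0 = time.perf_counter()
        try:
            cache = FoldCache(engine)
            sites = scan_sites(rec.sequence, config.matrix)
            ens = build_ensemble(
                rec.sequence, sites, cache, config.ensemble_params(), record_id=rec.id
            )
            entry: dict = {
                "n_sites": len(sites),
                "sites": [_site_row(s) for s in sites],
                "M": ens.M,
            }
            if ens.top_k:
                entry["ensemble"] = ensemble_summary(ens)
                entry["top_k"] = [_conformation_row(c) for c in ens.top_k]
                call = regulate_record(rec, ens, cache, config.translation)
                entry["regulation"] = {
                    "verdict": call.verdict,
                    "label_mass": call.label_mass,
                    "calls": [dataclasses.asdict(c) for c in call.calls],
                }
                pockets = flag_flexible_pockets(
                    build_pockets(ens.top_k), config.flexible_low, config.flexible_high
                )
                entry["pockets"] = [
                    {
                        "index": p.index,
                        "span": p.span,
                        "n_sites": p.n_sites,
                        "n_consensus": p.n_consensus,
                        "n_nonconsensus": p.n_nonconsensus,
                        "flexible": p.flexible_flag,
                    }
                    for p in pockets
                ]
                ensembles.append(ens)
                analyzed_records.append(rec)
            else:
                entry["regulation"] = {"verdict": "not_assessable"}
                entry["note"] = "no two-site conformation"
            entry["seconds"] = round(time.perf_counter() - t0, 4)
            report["records"][rec.id] = entry
        except Exception as exc:  # per-record isolation
            log.exception("record %s failed", rec.id)
            report["failures"][rec.id] = f"{type(exc).__name__}: {exc}"
    if ensembles:
        counts = classify_conformations(
            ensembles,
            coop_energy=config.strong_coop_energy,
            coop_max_d=config.strong_coop_max_d,
            structure_change=config.large_structure_change,
        )
        report["cohort"] = {
            "contingency": {
                "total": counts.total,
                "total_structure": counts.total_structure,
                "total_coop": counts.total_coop,
                "strata": counts.strata,
            },
            "sd_overlap": sd_overlap_report(analyzed_records, ensembles, config.translation),
        }
    return report


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
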