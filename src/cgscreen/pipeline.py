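"""End-to-end pipeline orchestration with a provenance manifest.

``pipeline_run`` executes simulate -> score -> classify -> liquid
validation -> enrichment and writes every intermediate table plus a JSON
manifest (package version, config, seeds, SHA-256 digests of every
output) so a run can be verified as reproducible by digest equality.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__, io, ntgv as ntgv_mod, scoring, synth
from .config import RunConfig
from .enrich import enrich

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def pipeline_run(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic-screen analysis; returns the manifest dict.

    Stage failures abort with the stage name in the exception; outputs of
    completed stages are left in place.
    """
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done = []

    def _stage(name):
        logger.info("stage: %s", name)
        stages_done.append(name)

    try:
        _stage("simulate")
        growth, truth, layouts = synth.simulate_screen(cfg.sim)
        io.write_growth_table(growth, out / "growth.tsv")
        io.write_truth_table(truth, out / "truth.tsv")
        io.write_plate_maps(layouts, out / "plate_maps.tsv")

        _stage("score")
        results, qc = scoring.score_screen(
            growth,
            layouts,
            bins=cfg.bins,
            sensitive_cut=cfg.sensitive_cut,
            resistant_cut=cfg.resistant_cut,
            wt_reference=cfg.wt_reference,
        )
        io.write_results_table(results, out / "screen_results.tsv")
        if qc is not None:
            qc.to_frame().to_csv(out / "plate_qc.tsv", sep="\t", index=False)

        _stage("classify")
        hits = results.loc[results["classification"] == "sensitive", "strain_id"]
        resistant = results.loc[results["classification"] == "resistant", "strain_id"]
        hits.to_csv(out / "sensitive_strains.txt", index=False, header=False)
        resistant.to_csv(out / "resistant_strains.txt", index=False, header=False)
        metrics = scoring.confusion_metrics(truth, results)

        _stage("validate")
        val_strains = truth[truth["strain_id"].isin(hits)].head(80)
        od = synth.simulate_od600(cfg.sim, val_strains)
        io.write_od_table(od, out / "od600.tsv")
        ntgv_res = ntgv_mod.ntgv_table(
            od,
            sensitive_cut=cfg.ntgv_sensitive_cut,
            resistant_cut=cfg.ntgv_resistant_cut,
        )
        ntgv_res.to_csv(out / "ntgv_results.tsv", sep="\t", index=False)
        n_val = int((ntgv_res["classification"] == "sensitive").sum())

        _stage("enrich")
        sets = synth.make_annotation_sets(truth, seed=cfg.seed)
        io.write_gmt(sets, out / "annotation_sets.gmt")
        enr = enrich(
            set(hits),
            set(truth["strain_id"]),
            sets,
            min_term_size=cfg.min_term_size,
            max_term_size=cfg.max_term_size,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        _stage("report")
        outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "package": "cgscreen",
            "version": __version__,
            "python": sys.version.split()[0],
            "pandas": pd.__version__,
            "config": cfg.to_dict(),
            "stages": stages_done,
            "n_sensitive": int(len(hits)),
            "n_resistant": int(len(resistant)),
            "recovery": metrics,
            "ntgv_validated_sensitive": n_val,
            "ntgv_tested": int(ntgv_res["strain_id"].nunique()),
            "top_enriched_term": str(enr.iloc[0]["term_id"]) if len(enr) else "",
            "digests": {p.name: _sha256(p) for p in outputs},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stages_done[-1]!r}: {exc}") from exc
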