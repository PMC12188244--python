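"""End-to-end orchestrator: simulate -> waveform -> stats -> DE ->
enrichment -> candidates, with a reproducibility manifest."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import candidates as cand
from . import dge, enrich, group_stats, synth
from .config import PipelineConfig
from .io import write_tsv
from .waveform import WaveformFeatures, features_from_recordings

log = logging.getLogger("eodkit")

# fixed per-stage spawn keys: stage i uses SeedSequence(seed, spawn_key=(1000+i,))
_STAGE_IDS = {"cohort": 0, "counts": 1, "genesets": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1000 + _STAGE_IDS[stage],))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: PipelineConfig,
    outdir,
    simulate: bool = True,
    counts: Optional[pd.DataFrame] = None,
    treatments: Optional[pd.Series] = None,
    library: Optional[enrich.GeneSetLibrary] = None,
) -> dict:
    """Execute every stage; write TSV outputs plus a run manifest.

    With ``simulate=True`` (the default and currently the only supported
    input mode for the waveform arm) all inputs are generated with seeds
    derived deterministically from ``config.seed``.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scale = config.simulate
    written: dict[str, Path] = {}
    stage = "setup"

    try:
        # --- waveform arm -------------------------------------------------
        stage = "cohort"
        log.info("stage %s", stage)
        design = synth.CohortDesign(
            days={
                "control": tuple(scale.days),
                "T1day": tuple(d for d in scale.days if d <= 1),
                "T8day": tuple(scale.days),
            },
            snippets_per_session=scale.snippets_per_session,
            seed=stage_seed(config.seed, "cohort"),
        )
        cohort = synth.simulate_cohort(design, cfg=config.detection)
        write_tsv(cohort.truth, outdir / "cohort_truth.tsv")
        written["cohort_truth"] = outdir / "cohort_truth.tsv"

        stage = "waveform"
        log.info("stage %s", stage)
        rows = []
        for (fish, day), recs in cohort.recordings.items():
            feats = features_from_recordings(recs, config.detection)
            rows.append(
                {
                    "fish": fish,
                    "treatment": recs[0].meta["treatment"],
                    "day": day,
                    "n_snippets": len(recs),
                    **feats.as_dict(),
                }
            )
        features = pd.DataFrame(rows).sort_values(["fish", "day"]).reset_index(drop=True)
        write_tsv(features, outdir / "features.tsv")
        written["features"] = outdir / "features.tsv"

        stage = "stats"
        log.info("stage %s", stage)
        stat_rows = []
        for when, frame in (
            ("day0", features[features["day"] == 0]),
            ("last", features.loc[features.groupby("fish")["day"].idxmax()]),
        ):
            summary = group_stats.feature_group_table(
                frame, list(WaveformFeatures.FIELDS), alpha=config.stats.alpha
            )
            summary.insert(0, "when", when)
            stat_rows.append(summary)
        stats_table = pd.concat(stat_rows, ignore_index=True)
        write_tsv(stats_table, outdir / "stats.tsv")
        written["stats"] = outdir / "stats.tsv"

        # --- expression arm ----------------------------------------------
        stage = "counts"
        log.info("stage %s", stage)
        if simulate or counts is None:
            expr_params = synth.ExprSimParams(
                n_genes=scale.n_genes,
                planted_degs=synth.random_planted_degs(
                    scale.n_genes,
                    scale.planted_per_class,
                    scale.effect,
                    seed=stage_seed(config.seed, "counts"),
                ),
                seed=stage_seed(config.seed, "counts"),
            )
            sim = synth.simulate_counts(expr_params)
            counts, treatments = sim.counts, sim.treatments
            write_tsv(sim.truth, outdir / "deg_truth.tsv")
            written["deg_truth"] = outdir / "deg_truth.tsv"
            counts.rename_axis("gene").reset_index().to_csv(
                outdir / "counts.tsv", sep="\t", index=False
            )
            written["counts"] = outdir / "counts.tsv"
        if treatments is None:
            raise ValueError("treatments must accompany an external count matrix")

        stage = "dge"
        log.info("stage %s", stage)
        tables = dge.run_contrasts(counts, treatments, config.dge.expressed_min_prop)
        calls = {}
        n_expressed = {}
        for name, table in tables.items():
            write_tsv(table.reset_index(drop=True), outdir / f"de_{name}.tsv")
            written[f"de_{name}"] = outdir / f"de_{name}.tsv"
            calls[name] = dge.filter_degs(table, config.dge.min_fc, config.dge.max_fdr)
            n_expressed[name] = len(table)
        patterns = dge.classify_patterns(calls)
        write_tsv(patterns.rename_axis("gene").reset_index(), outdir / "patterns.tsv")
        written["patterns"] = outdir / "patterns.tsv"
        summary = dge.summarize_contrasts(calls=calls, n_expressed=n_expressed)
        write_tsv(summary.reset_index(drop=True), outdir / "contrast_summary.tsv")
        written["contrast_summary"] = outdir / "contrast_summary.tsv"

        stage = "enrich"
        log.info("stage %s", stage)
        if simulate or library is None:
            specs = {}
            kinds = [(p, d) for p in synth.PATTERNS for d in synth.DIRECTIONS]
            for i in range(scale.n_enriched_sets):
                p, d = kinds[i % len(kinds)]
                specs[f"ENRICHED_{p}_{d}_{i:02d}"] = synth.EnrichedSetSpec(
                    pattern=p, direction=d, size=max(20, scale.planted_per_class)
                )
            gs_params = synth.GeneSetSimParams(
                n_sets=scale.n_sets,
                enriched_sets=specs,
                seed=stage_seed(config.seed, "genesets"),
            )
            truth_for_sets = (
                sim.truth if simulate else pd.DataFrame(columns=["gene", "pattern", "direction"])
            )
            library, set_truth = synth.simulate_geneset_library(
                gs_params, truth_for_sets, list(counts.index)
            )
            write_tsv(set_truth, outdir / "geneset_truth.tsv")
            written["geneset_truth"] = outdir / "geneset_truth.tsv"
            library.write_gmt(outdir / "library.gmt")
            written["library"] = outdir / "library.gmt"

        profiles = enrich.build_profiles(
            {dge.CONTRAST_ROLES[name]: t for name, t in tables.items()}
        )
        scores = enrich.score_gene_sets(profiles, library, config.enrichment.minsetsize)
        enriched = enrich.filter_enriched(
            scores, config.enrichment.max_fdr, config.enrichment.min_s
        )
        selected = enrich.select_gene_sets(enriched, config.enrichment.delta)
        scores = scores.assign(
            enriched=scores["set"].isin(enriched["set"]),
            selected=scores["set"].isin(selected["set"]),
        )
        write_tsv(scores.reset_index(drop=True), outdir / "enrichment.tsv")
        written["enrichment"] = outdir / "enrichment.tsv"

        stage = "candidates"
        log.info("stage %s", stage)
        cand_table, excluded = cand.derive_candidates(
            select_sets=list(selected["set"]),
            library=library,
            calls=calls,
            tables=tables,
        )
        write_tsv(cand_table, outdir / "candidates.tsv")
        written["candidates"] = outdir / "candidates.tsv"
        write_tsv(excluded, outdir / "candidates_excluded.tsv")
        written["candidates_excluded"] = outdir / "candidates_excluded.tsv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {
            name: {
                "path": path.name,
                "sha256": _sha256(path),
                "rows": max(0, sum(1 for _ in open(path)) - (0 if path.suffix == ".gmt" else 1)),
            }
            for name, path in written.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
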