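# eodkit

Analysis pipeline for androgen-induced electric organ discharge (EOD)
elongation experiments: EOD waveform feature extraction, longitudinal group
statistics, three-contrast differential-expression filtering and pattern
classification, multi-contrast rank-based gene-set enrichment, and
candidate-gene selection — plus synthetic-data generators with known ground
truth so the whole pipeline is testable without any external data.

## Layout

| module | role |
|---|---|
| `eodkit.synth` | synthetic pulse snippets, longitudinal cohorts, negative-binomial count matrices with planted DEGs, gene-set libraries with planted enrichment |
| `eodkit.waveform` | baseline correction, peak-to-peak normalization, peak alignment, averaging; threshold-crossing pulse bounds; the seven waveform parameters (durations, vP2/vP1, P1–P2 delay, sP1, exponential decay constant tau) |
| `eodkit.group_stats` | trailing-window CV acclimation rule, one-way ANOVA, Tukey HSD with compact letter display |
| `eodkit.dge` | TMM normalization, a documented stand-in DE test (Welch's t on log2 CPM), Benjamini–Hochberg FDR, FC/FDR significance filter, broad/early/late pattern classification, contrast summaries, sample correlation |
| `eodkit.enrich` | GMT I/O, directional rank profiles, per-contrast enrichment score s in (−1, 1), multi-contrast score S, MANOVA (Pillai) significance, enrichment and select-set filters |
| `eodkit.candidates` | select-set ∩ DEG intersection, manual additions, early-only and blacklist exclusions |
| `eodkit.config` / `eodkit.pipeline` / `eodkit.cli` | validated YAML/JSON config, end-to-end orchestrator with run manifest, command-line interface |

The DE test is deliberately a simple, documented stand-in (not a
negative-binomial GLM); externally produced per-contrast tables with columns
`gene, log2fc, pvalue, fdr, mean_expr` are accepted as first-class input by
the enrichment and candidate stages.

## CLI

```sh
eodkit run-all --out out/ --seed 1            # full synthetic end-to-end run
eodkit simulate --out sim/ --seed 1           # write synthetic inputs
eodkit waveform --in sim/recordings --out features.tsv
eodkit stats --features features.tsv --out stats.tsv
eodkit dge --counts sim/counts.tsv --out-dir de/
eodkit enrich --gmt sim/library.gmt --de-dir de/ --out enrichment.tsv
eodkit candidates --enrichment enrichment.tsv --gmt sim/library.gmt \
    --de-dir de/ --out candidates.tsv
```

All thresholds (detection windows, FC/FDR cutoffs, enrichment filters) live
in a YAML config; see `eodkit.config.PipelineConfig` for defaults. Every
stage derives its random seed deterministically from the run seed, and
`run-all` writes a `manifest.json` with config snapshot, output checksums
and row counts; identical seeds give byte-identical outputs.

## Data formats

Recordings are single-column voltage CSVs with a JSON sidecar
(`sample_rate`, `npts`, fish, treatment, day); tables are TSV; gene-set
libraries are GMT.
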