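# accesspanel

Chromatin-accessibility-aware design and validation of liquid-biopsy
targeted-sequencing panels.

Tumor-derived cfDNA competes with an overwhelming background of blood-cell
fragments. This package scores genomic regions by their *relative
accessibility* — log2 of mean normalized tumor ATAC-seq counts over a 2:1
neutrophil:PBMC weighted blood mean — and uses that score to (a) design
cancer-specifically accessible or inaccessible targeted panels via a
RF / linear-SVM / L1-logistic consensus feature-selection pipeline, (b) rank
known markers (mutations, DMRs) for inclusion in panels, and (c) validate
panels against cfDNA fragmentation patterns and tumor–cfDNA allele-frequency
concordance.

## Modules

| module | purpose |
|---|---|
| `accesspanel.intervals` | peak data model, summit extension, blacklist filtering, score-per-million normalization, iterative non-overlapping consolidation, overlap queries |
| `accesspanel.blood` | cell-type-specific peak sets, consensus blood peak set, weighted blood mean, accessibility quartiles |
| `accesspanel.scoring` | count matrices, CPM normalization, relative accessibility score |
| `accesspanel.panel` | score/blood-overlap filters, negative-binomial differential accessibility (BH-corrected), 5-fold CV consensus feature selection, classifier evaluation, `design_panel` |
| `accesspanel.fragmentation` | per-region cfDNA fragment depth & median length, Welch comparison, Savitzky–Golay smoothing, accessibility–fragmentation correlation |
| `accesspanel.markers` | marker ranking by score, variant quality/germline filters, AF concordance split by score sign |
| `accesspanel.simulate` | seeded generators for every pipeline input, with truth tables |
| `accesspanel.io` / `accesspanel.cli` | text-format readers/writers (BED, narrowPeak, TSV, minimal VCF, JSON) and the CLI |

## CLI

```sh
# generate a full synthetic input bundle with truth tables
accesspanel simulate --seed 1 --out-dir sim/

# consensus blood peak set from per-sample narrowPeak calls
accesspanel blood-consensus --samples sim/blood_peak_samples.tsv --out-dir blood/

# per-region relative accessibility for one cancer type
accesspanel score --counts sim/counts.tsv --samples sim/samples.tsv \
    --cancer-type cancerA --out scores.tsv

# accessible (or inaccessible) panel design
accesspanel design-panel --direction accessible \
    --counts sim/counts.tsv --samples sim/samples.tsv \
    --blood-peaks blood/consensus_blood.bed --scores scores.tsv \
    --regions sim/regions.bed --cancer-type cancerA --seed 1 --out-dir panel/

# cfDNA fragmentation validation
accesspanel fragmentation --fragments sim/fragments_healthy.bed \
    --regions sim/regions.bed --scores scores.tsv --out-dir frag/

# marker ranking and tumor-cfDNA AF concordance
accesspanel rank-markers --markers markers.tsv --peaks sim/regions.bed \
    --scores scores.tsv --out ranked.tsv
accesspanel af-concordance --tumor sim/variants_tumor.tsv \
    --cfdna sim/variants_cfdna.tsv --peaks sim/regions.bed \
    --scores scores.tsv --out concordance.json
```

Every subcommand writes a `manifest.json` recording parameters, inputs and
seed; identical seeds and inputs produce byte-identical data outputs.

## Conventions

- Coordinates are 0-based half-open (BED); overlap means ≥ 1 shared bp.
- Variant positions are 1-based (VCF) and converted internally.
- Fixed peak width is `2·flank + 1` (summit base included); edge-clipped
  peaks are flagged, not dropped.
- All tabular output is TSV with floats at 6 significant digits; BED scores
  are browser-clamped to 0–1000 with a full-precision `.scores.tsv` sidecar.
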