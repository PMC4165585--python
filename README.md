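# methpanel

A toolkit for building and evaluating DNA-methylation biomarker panels for
B-cell lymphoma, covering the full workflow:

1. **Candidate selection** (`methpanel.candidate_selection`) — three-criteria
   screen over a log2 expression matrix: genes down in patients of one
   lymphoma type, re-expressed after demethylating treatment of that type's
   cell lines, and with a type-specific treatment response.
2. **Bisulfite trace scoring** (`methpanel.bisulfite_scoring`) — per-CpG
   C/(C+T) ratios bucketed at 0.20/0.80 into unmethylated / partial / full,
   MSP duplicate-run consensus, and cell-line frequency tables.
3. **qMSP quantification** (`methpanel.qmsp_quant`) — per-assay standard
   curves (Ct vs log10 quantity), replicate averaging on the quantity scale,
   ALU-C4 input normalisation, and percent-methylated-reference (PMR)
   against a fully methylated calibrator.
4. **Panel statistics** (`methpanel.panel_stats`) — control-calibrated
   positivity threshold (ceiling of the control maximum), frequency tables
   with pooled rows, Fisher's exact and Mann–Whitney tests, summed-PMR panel
   scores, and ROC/AUC via the midrank U identity.
5. **Synthetic data** (`methpanel.synthio`) — seeded generators for all four
   input tables with planted ground truth (candidate genes, per-group
   methylation frequencies, true PMRs, trace levels), so the pipeline is
   fully exercisable and parameter recovery is testable offline.

All tables are plain TSV with `#` metadata preambles (tool version, seed,
config hash); runs are deterministic given a seed.

## CLI

```sh
methpanel simulate --outdir out --seed 1           # synthetic input tables
methpanel select --expr out/expression.tsv --meta out/meta.tsv \
    --top 24 --out out/candidates.tsv
methpanel score-bisulfite --traces out/traces.tsv --out out/cpg_calls.tsv
methpanel msp-table --bands bands.tsv --grouping grouping.tsv --out freq.tsv
methpanel quantify --plate out/plate.tsv --out out/pmr.tsv
methpanel panel --pmr out/pmr.tsv --cohort out/cohort.tsv \
    --genes LRP12,CDH1,BMPER,DUSP4,BMP7 --threshold auto --out out/panel
methpanel run --config run.yaml                    # full pipeline
```

A minimal `run.yaml`:

```yaml
outdir: out
seed: 1
simulate: {}          # or an inputs: block with paths to the four tables
panel:
  threshold: auto
```

## Tests and acceptance report

```sh
python -m pytest -q                 # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline frequency-table percentages
and the threshold calibration from published per-group counts by running
them through the package, and writes one JSON entry per target.
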