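# propensity-screen

Marker discovery for cell-line differentiation propensity, plus two-group
beta-value differential methylation, as a tested, reusable package. The
pipeline:

1. **synthetic data** — generates expression arrays, a trilineage qPCR marker
   panel, and a two-group methylation dataset with planted statistical
   structure (latent lineage propensities with configurable rank coupling,
   probes planted at target Spearman correlations, gene-body
   hypermethylation), so every downstream stage is testable offline.
2. **filtering** — global scaling of each array to a trimmed mean of 500
   (2% per tail), then a three-step probe filter: present calls in >= 4 of 6
   replicates in at least one line, one-way ANOVA across lines at P < 0.05,
   and a >= 5-fold max/min ratio of line-mean intensities.
3. **ranking** — comparative-Ct quantification (GAPDH housekeeping,
   fold changes normalized to the average of the reference line), per-gene
   z-scoring, PCA per germ-layer marker panel, and descending-PC1 ranking of
   the cell lines.
4. **marker screen** — each surviving probe's line-mean expression rank is
   correlated against each lineage's propensity rank; significance uses the
   *exact* permutation null of Spearman's r_s at the number of lines (the
   two-sided 5% critical value at n = 10 is 0.648). Signed candidate sets
   are intersected at the gene level to find switch markers that correlate
   positively with one lineage and negatively with the others.
5. **methylation** — detection-P and annotation filters, per-probe two-sample
   t-tests with Benjamini–Hochberg correction, hyper/hypo classes from the
   joint q < 0.05 and |log2 fold-change| > 0.6 thresholds, a seven-category
   genomic-region distribution, and per-gene island/shore tracks.

## Command line

```bash
# full synthetic end-to-end run
propensity-screen run --seed 7 --out-dir results/run7

# individual stages
propensity-screen simulate --seed 3 --out-dir data/
propensity-screen filter --intensity data/expression_intensity.tsv \
    --calls data/expression_calls.tsv --out-dir results/
propensity-screen rank --ct-table data/ct_table.tsv --panels data/panels.csv \
    --out-dir results/
propensity-screen screen --intensity data/expression_intensity.tsv \
    --calls data/expression_calls.tsv --probes results/surviving_probes.tsv \
    --ranking-ct-table data/ct_table.tsv --panels data/panels.csv \
    --annotation data/gene_map.tsv --out-dir results/
propensity-screen methylation --beta data/beta.tsv \
    --detection-p data/detection_p.tsv --manifest data/manifest.csv \
    --out-dir results/
```

`run` and `simulate` accept `--config config.yaml`; top-level keys mirror
`PipelineConfig` fields and a `simulation:` block mirrors
`SimulationConfig`. Exit codes: 0 success, 2 configuration error, 3 file
format error, 4 analysis error.

## File formats

All files are header-bearing UTF-8. Expression travels as a TSV pair
(intensities and P/A/M calls) with a `probe_id` column followed by
`<line>_<rep>` sample columns. The qPCR table is long-format TSV
(`line, replicate, gene, well, ct`); panels are CSV (`gene, lineage`).
Methylation uses beta and detection-P TSVs (`<group>_<rep>` columns) and a
manifest CSV with HM450-style columns (`IlmnID, CHR, MAPINFO,
UCSC_RefGene_Name, UCSC_RefGene_Group, Relation_to_UCSC_CpG_Island`;
MAPINFO is 1-based).

## Layout

```
src/propensity_screen/
  synthetic.py    planted-structure input generator
  filtering.py    global scaling + three-step probe filter
  ranking.py      comparative Ct, z-scoring, PCA, line ranking
  exact_null.py   exact permutation null of Spearman's r_s
  screen.py       marker screen, intersections, top-k tables
  methylation.py  differential methylation + region categorization
  io.py           TSV/CSV/JSON readers and writers
  pipeline.py     end-to-end orchestration + run report
  cli.py          click CLI (propensity-screen)
```
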