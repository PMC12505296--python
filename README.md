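# motifdms

Deep mutational scanning (DMS) of a short linear binding motif, scored by
DHFR protein-fragment complementation (PCA) growth selection.

In the assay this package analyzes, nearly every single-codon variant of a
motif-carrying region — here the SH3-binding motif of the yeast MAP kinase
kinase Pbs2 (canonical motif KPLPPLP at residues 93–99) and its flanks —
competes in one pool. Each variant's prey protein is fused to a DHFR
fragment; the bait (the SH3-domain osmosensor Sho1, or the abundance
control Hog1) carries the complementary fragment. Binding reconstitutes
DHFR and lets the cell divide under methotrexate (MTX), so a variant's
change in pool frequency across selection reads out its interaction
strength in vivo.

`motifdms` implements the full analysis path, plus a seeded synthetic-data
generator with the same statistical structure, so every stage is testable
without any sequencing data:

- **library_design** — enumerate and annotate NNN/NNK single-codon variant
  libraries of an ORF region.
- **synthetic_data** — pooled competition counts under multiplicative
  per-generation fitness `f_post ∝ f_pre · 2^{(b_v·[MTX, Sho1 bait] + a_v)·g}`,
  barcoded FASTQ reads with per-base errors, OD trajectories, and
  1,536-format colony grids with plate/row/column bias.
- **variant_calling** — demultiplex on row/column barcodes (≤1 substitution,
  unique), collapse identical reads, global Needleman–Wunsch alignment to
  the wild-type sequence (EMBOSS-needle-like scoring), single-codon variant
  calls, count tables.
- **scoring** — interaction score = log2 fold-change of variant frequency
  across selection, rescaled per library so the wild type is 0 and the
  nonsense median is exactly −1; ≥20-read count filter; per-amino-acid
  medians over ≥3 surviving replicate measurements; selection coefficients
  with generations counted as log2 OD fold-change.
- **stat_filters** — the Mann–Whitney U / Benjamini–Hochberg cascade:
  control-outlier removal, control-condition defect removal, Hog1-based
  abundance exclusion, stronger/weaker/not-different classification, and a
  Welch's t proliferation test.
- **growth_curves** — maximal growth rate as the 98th percentile of
  5-point-window log2-OD slopes; fragment interaction scores relative to a
  fragment-free control.
- **colony_pca** — solid-media colony arrays: filtering, log2 + plate
  centering + row/column median polish, rescaling to stuffer = 0 /
  wild-type reference = 1, one-sided bait comparisons.
- **cli_io** — schema-validated TSV I/O (`NA` missing values, audit
  headers), YAML pipeline configs, and the `motifdms` command-line tool.

## Worked example

Run the bundled synthetic pipeline end to end (simulate → emit reads →
call variants → score → filter/classify):

```python
from motifdms import cli_io

config = cli_io.PipelineConfig(
    out_dir="demo", seed=1,
    sim={"read_depth": 20000, "n_replicates": 3,
         "conditions": ["MTX+sorbitol", "noMTX"],
         "baits": ["Sho1", "Hog1"],
         "couple_abundance_to_growth": True},
)
artifacts = cli_io.run_pipeline(config)
print(artifacts["summary"])
```

prints

```
{'n_score_records': 6048, 'n_pass_count_filter': 6048,
 'n_records_in': 6048, 'n_control_outliers': 6,
 'n_control_condition_defects': 0, 'n_abundance_excluded': 0,
 'n_records_out': 2988, 'n_classified': 304,
 'n_stronger': 29, 'n_weaker': 184, 'n_not_different': 91}
```

6,048 replicate-level score records enter the cascade (2 baits × 2
conditions × 3 replicates × 504 library members); 6 nonsense/silent
controls are flagged as outliers and removed; of the 304 missense
amino-acid changes classified against the pooled wild-type and synonymous
scores, 29 bind significantly more strongly and 184 significantly more
weakly than wild type — close to the planted 10% / 60% fractions of the
default synthetic effect landscape. `demo/aa_scores_classified.tsv` then
holds one row per amino-acid change, e.g.

```
bait  condition     aa_change_key  score   n_contributing  p_adj    classification
Sho1  MTX+sorbitol  A-100-D        0.394   3               0.0073   stronger
Sho1  MTX+sorbitol  A-100-C        -0.109  3               0.386    not_different
```

where `score` is the median rescaled interaction score (0 = wild type,
−1 = nonsense median). The same stages are available as subcommands:
`motifdms run|simulate|call-variants|score|filter-classify|growth|colony`.

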