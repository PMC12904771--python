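# divorph

Simulation-driven classification of **orphan proteins that diverged
beyond recognition**. Orphan genes have no detectable homologues outside
a taxon, but orphans born by divergence often retain *non-significant*
similarity hits in the "twilight zone". `divorph` simulates protein
divergence to the edge of detectability, harvests statistical features
from those discarded hits, and trains explainable classifiers that
separate diverged orphans from reversed-sequence (homology-free)
controls. The fitted ensemble can then score real orphan hit tables.

## What's inside

| module | role |
| --- | --- |
| `divorph.io_formats` | FASTA, 12-column tabular hits (BLAST/DIAMOND `-outfmt 6`), newick |
| `divorph.lg_data` | embedded LG substitution-model constants |
| `divorph.evolver` | LG + gamma-rates + invariant-sites + indel divergence simulator along a tree |
| `divorph.minisearch` | desk-scale Smith–Waterman search with Karlin–Altschul E-values (numba-accelerated) |
| `divorph.orphan_pipeline` | eligibility band filtering, reversal controls, truncation calibration, balanced dataset assembly |
| `divorph.features` | the 11 band-hit features + z-score scaling |
| `divorph.classify` | Bayes / logistic regression / random forest / gradient boosting, grid search, metrics, importances, 2-of-3 ensemble vote |
| `divorph.stats_compare` | enrichment chi-squared (Yates), rank-sum tests, Cohen's d, length-controlled re-test |
| `divorph.fixtures` | fully synthetic roots/decoys and named end-to-end scenarios |

External aligner output is interchangeable: any `-outfmt 6` file can be
fed to `orphans`/`featurize` in place of the built-in searcher.

## CLI

```bash
# simulate divergence of root proteins along the fixed 4-taxon tree
divorph simulate --roots roots.faa --alpha 0.1 --indel-rate 0.005 \
    --seed 7 --out-dir sim/

# search queries against a database (or use external DIAMOND output)
divorph search --query sim/Taxon1.faa --db db.faa --evalue 1.0 --out hits.tsv

# eligibility calls and band-hit features
divorph orphans  --hits hits.tsv --queries sim/Taxon1.faa --out calls.tsv
divorph featurize --hits hits.tsv --queries sim/Taxon1.faa --label 1 \
    --out feats.tsv

# train the four classifiers (--full-grid for the complete sweep)
divorph train --features labeled.tsv --seed 1 --models-dir models/ \
    --report report.json

# ensemble divergence calls on new feature tables
divorph predict --features real.tsv --models-dir models/ --out preds.tsv

# downstream statistics
divorph stats enrich --calls preds.tsv --subset denovo_ids.txt
divorph stats compare --calls preds.tsv --annotations props.tsv \
    --property disorder

# one-shot synthetic end-to-end scenario
divorph fixtures make --scenario favorable --seed 7 --out bundle/
```

## Notes & knobs

* Branch lengths are in expected substitutions/site (the generator is
  normalized), so the fixed tree's terminal branches read 1/3/5/10.
* The indel length law is geometric (mean configurable, default 3); the
  single published indel rate is applied to insertions and deletions
  alike. Both are documented knobs, not published constants.
* The invariant-sites proportion defaults to 0; its published effect is
  negligible (the source material quotes both 0.001 and 0.1 variants).
* Z-scores are fitted on the training split by default (leak-free);
  `--scale-on-all` reproduces whole-table scaling.
* Default hyperparameter grids are reduced for desk-scale runtime;
  `--full-grid` switches to the complete replication sweep.
* Desk-scale scenarios scale the tree (×5) so that low-alpha regimes
  still yield eligible orphans against small databases; see the
  `divorph.fixtures` docstring.
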