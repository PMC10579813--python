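# syndiff

Multi-label syndrome differentiation from clinical symptom records.

A record is a set of symptom terms plus a set of syndrome labels. `syndiff`
turns delimited-text record files into sparse design matrices and classifies
each record into one or more syndromes with a two-stage method:

1. **Feature selection** (`syndiff.relieff`) — a multi-label ReliefF variant
   that weights neighbor contributions by the reciprocal of the Pearson
   distance between samples (`sim = 1/(1 − ρ)`), visits every sample once as
   a probe, and ranks features by how well they separate unlike label sets.
   A cosine-similarity mode is kept as an ablation baseline.
2. **Cascade forest** (`syndiff.cascade`) — layers of two multi-label forest
   groups (variance-reduction "predictive clustering" trees and Gini trees),
   each layer feeding its out-of-fold class-vector representation to the
   next, with per-instance measure-aware representation reuse and growth
   that stops after three layers without improvement in the tracked measure.

Supporting modules: `corpus_io` (reading/cleaning/merging/standardizing
records, TF-IDF or binary vectorization, text-based matrix round-trips),
`metrics` (six rank/label measures + five instance-set measures, all
cross-checked against brute-force oracles), `synthetic` (generator with
planted informative features, Zipf label marginals and controllable label
co-occurrence), `cli` (end-to-end cross-validated orchestration).

## CLI

```bash
# generate a synthetic dataset (with spelling variants + synonym dictionary)
syndiff synth --out data_dir --n 200 --m 6 --variant-rate 0.2 --seed 1

# clean, merge, standardize, vectorize
syndiff preprocess --records data_dir/records.tsv --synonyms data_dir/synonyms.tsv \
    --out prep --scheme tfidf

# rank features and keep the best quarter
syndiff select --records data_dir/records.tsv --out sel --k 10

# fit on the whole file and save the model
syndiff fit --records data_dir/records.tsv --out fitdir --n-select 50 --seed 1

# score new records with a saved model
syndiff evaluate --records data_dir/records.tsv --model fitdir/model --out evaldir

# 5-fold cross-validated pipeline (selection + TF-IDF refit inside each fold)
syndiff run --records data_dir/records.tsv --out cv --folds 5 --seed 1

# paired comparison: cascade alone vs selection + cascade on identical folds
syndiff ablate --records data_dir/records.tsv --out abl --seed 1
```

Record files are delimited text: two columns (symptoms, labels), terms
separated by `|` inside a cell; `--has-id` reads a leading record-id column.
The synonym dictionary is two-column TSV (`variant<TAB>standard`).

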