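# oriseq

Classification of DNA replication-origin sequences from fixed-length
(default 300 bp) two-class FASTA sets, one species at a time.

The pipeline:

1. **Feature extraction** — three encoders:
   - **TF-IDF** over the complete k-mer vocabulary for k = 1..6
     (4 + 16 + … + 4096 = 5460 tuples). Term frequency is the tuple's share
     of all tuple occurrences in the *positive* training sequences; IDF is
     `log(|D| / (1 + df))` over all training sequences. A sequence is encoded
     as `tfidf_i × n_i` with `n_i` its own tuple count.
   - **Base content** — AT-profile, GC-profile, GC-skew, AT-skew per sequence.
   - **PseKNC type II** (series correlation) — normalized k-mer frequencies
     plus tiered dinucleotide-property correlation factors (six bundled
     B-DNA step parameters, z-scored; table is user-replaceable).
2. **Feature selection** — rank by F-score (or by the TF-IDF weights for
   TF-IDF columns), then incremental feature selection: evaluate nested
   top-j subsets with a cross-validated SVM and keep the j with the best
   mean accuracy.
3. **Modeling** — SVM / MLP / KNN / decision tree / naive Bayes / gradient
   boosted trees with published tuning grids, evaluated by repeated
   stratified 5-fold cross-validation reporting Sn, Sp, Acc, MCC and AUC
   (means ± SD over repeats, confusions pooled per repeat).
4. **Cross-species transfer** — a trained model plus its frozen feature
   pipeline (vocabulary, TF-IDF weights, selected columns) applied verbatim
   to another species' sequences.
5. **Synthetic data** — a seeded generator of balanced two-class sets with
   planted motifs and/or composition-skew offsets, so the full pipeline is
   testable without any downloads.

## CLI

Each stage is a subcommand of `oriseq`:

```sh
# make a synthetic species (two FASTA files + provenance sidecar)
oriseq synth --n-positive 100 --n-negative 100 --motif GGG --copies 3 \
    --seed 7 --species demo --out data/

# extract features to a TSV matrix
oriseq extract --positive data/demo_positive.fasta \
    --negative data/demo_negative.fasta --species demo \
    --features base --out demo_features.tsv

# rank + incremental feature selection
oriseq select --matrix demo_features.tsv --rank fscore --out demo_sel

# grid-search hyperparameters, then repeated CV
oriseq tune --matrix demo_features.tsv --family knn --out demo_params.json
oriseq evaluate --matrix demo_features.tsv --family knn \
    --params demo_params.json --repeats 10 --out demo_eval

# everything end to end from one YAML config
oriseq run --config config.yaml

# apply a frozen model to another species
oriseq cross-species --model out/model.joblib \
    --positive other_pos.fasta --negative other_neg.fasta \
    --species other --out other_eval
```

A minimal `config.yaml` for `oriseq run`:

```yaml
positive: data/demo_positive.fasta
negative: data/demo_negative.fasta
species: demo
features: tfidf        # tfidf | pseknc | base | combo
rank: fscore           # fscore | tfidf
family: mlp            # svm | mlp | knn | decision_tree | naive_bayes | gradient_boosted_trees
repeats: 10
seed: 0
out: out/
```

`oriseq run` writes the split manifest, feature matrix, IFS curve, selected
features, tuned parameters, per-repeat CV report, held-out test summary,
a reloadable model archive and a manifest with seeds and the config hash.

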