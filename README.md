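# dialogi

Literature triage for drug-induced liver injury (DILI) style corpora:
classify title+abstract documents with a baseline (text-only) BiLSTM and an
extended model that also consumes chemical/disease concept embeddings.

The package implements the full pipeline:

1. **`dialogi.synthetic_data`** — generates every input with known planted
   structure: a two-class document table, PubTator-format annotations with
   exact character offsets, a term hierarchy, block-structured association
   tables and random word vectors.
2. **`dialogi.textproc`** — pre-processing (content-POS/length/stopword
   filters over lemmas), PubTator parsing, mention-to-token alignment with a
   90% character-overlap threshold, per-document concept relative
   frequencies, and processed-text export (plain / replace-by-id /
   replace-by-category).
3. **`dialogi.concept_spaces`** — concept embeddings from a hierarchy or
   association table: corpus construction → TF-IDF (df-filtered, ln(n/df)+1)
   → truncated SVD at a variance target → empirical-null cosine similarity
   network (−log10 p edge weights, forced 3 nearest neighbours) → node2vec
   (in-house weighted walks + skip-gram with negative sampling).
4. **`dialogi.space_compare`** — extrapolated Rank-Biased Overlap of
   nearest-neighbour lists and CCA-based Pearson correlation between spaces.
5. **`dialogi.features`** — composite spaces (concatenate → group-wise SVD →
   concatenate) and per-document feature vectors (frequency-weighted
   averages per category, unit-normalized, disease part first).
6. **`dialogi.classifier` / `dialogi.nn`** — NumPy BiLSTM classifiers
   (trainable embeddings initialised from pretrained vectors, masked
   padding, Adam, 1 epoch, batch 32) under nested cross-validation
   (10 outer / 5 inner stratified folds), the frozen-base extended model,
   macro/micro F1 evaluation and the threshold sweep.
7. **`dialogi.explore`** — normalize → PCA(15) → 3D t-SNE projection, and
   cosine-ranked retrieval against constructed concept queries with
   per-concept-pair explanations.

The neural network and node2vec are implemented from scratch in NumPy
(verified against numerical gradients and embedding-quality tests), so the
package has no deep-learning framework dependency.

## CLI walkthrough (synthetic end-to-end)

```bash
dialogi synth --n-docs 200 --seed 0 --out-dir data/
dialogi preprocess --docs data/docs.tsv --annotations data/anns.pubtator \
    --mode replace_id --out processed.tsv
dialogi embed-concepts --source association --in data/assoc_disease.tsv \
    --out disease.vec --dim 128 --seed 0
dialogi embed-concepts --source association --in data/assoc_chemical.tsv \
    --out chemical.vec --dim 128 --seed 0
dialogi compare-spaces --a disease.vec --b chemical.vec --out comparison.json
dialogi featurize --docs data/docs.tsv --annotations data/anns.pubtator \
    --disease-space disease.vec --chemical-space chemical.vec --out features.tsv
dialogi train --docs processed.tsv --features features.tsv \
    --vectors data/words.vec --outer 10 --inner 5 --seed 0 \
    --save-models --out runs/
dialogi evaluate --run runs/ --external-docs external_processed.tsv \
    --external-features external_features.tsv
dialogi explore project --features features.tsv --out coords.tsv
dialogi explore query --concepts D000001:1,D500001:2 --features features.tsv \
    --disease-space disease.vec --chemical-space chemical.vec --top 20
```

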