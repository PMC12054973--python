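# funcmatch

Multimodal protein–function matching: a binary classifier over
(protein sequence, function-description text) pairs that supports both
supervised and **zero-shot** function prediction, together with a synthetic
sequence–function world generator so the entire pipeline — loss, weighted
sampling, augmentations, ontology propagation, ensembling, baselines, and
metrics — runs and is testable on a single CPU with no downloads.

The package is for computational biologists and ML practitioners who work
on automated protein function annotation (Gene Ontology terms, EC numbers)
and want a compact, fully tested reference implementation of the
text-conditioned pair-scoring approach: instead of a fixed multi-label
output head, the model scores a protein against the *description* of a
candidate function, so new labels — functions described after training —
can be queried through their text alone.

## The model

Given a sequence embedding `s` (frozen sequence encoder) and a description
embedding `t` (frozen text encoder), two projection heads (MLPs with three
hidden layers of `3d` units, output size `d`, ReLU, batch norm, no biases)
map both to a common space; their concatenation is fused by a third MLP
into a single logistic output

    p(i, j) = P(sequence i is annotated with term j | s_i, t_j).

Training minimizes the focal loss

    FL = (1 − p_t)^γ · (−ln p_t),   p_t = p for true pairs, 1 − p otherwise,

with γ = 2 and no α weight, and draws sequences with probability
proportional to

    w_i = Σ_j δ_ij / √f_j,

the inverse square-root frequency of their annotated terms — both
mechanisms target the extreme label imbalance of annotation corpora.
Annotations are ancestor-inclusive: every protein's term set is closed
under the ontology DAG's parent relation before anything else sees it.
Three augmentations regularize training (BLOSUM62-conservative residue
substitution, random choice between a term's short and long description,
Gaussian noise on the label embedding); at inference the short- and
long-description scores are averaged. Evaluation is threshold-free macro /
micro mAP (AUPRC), with macro — each term weighted equally — used for model
selection. The network and optimizer are implemented in NumPy; see
`docs/methods.md` for the full account.

## Worked example

```python
from funcmatch import (ProteinFunctionClassifier, WorldConfig, generate_world,
                       evaluate, prevalence_baseline_ap)

# a synthetic world: 200 training sequences, 20 in-vocabulary terms,
# 6 held-out (zero-shot) terms defined by motif conjunctions
train, val, test, zero_shot, motifs = generate_world(WorldConfig())

clf = ProteinFunctionClassifier(random_state=1).fit(train, val=val)

print("supervised test mAP macro:", round(clf.score(test), 4))
print("zero-shot mAP macro:     ", round(clf.score(zero_shot), 4))
print("chance floor (prevalence):", round(prevalence_baseline_ap(zero_shot), 4))
```

Output (about two minutes on one CPU):

```
supervised test mAP macro: 0.6192
zero-shot mAP macro:      0.5342
chance floor (prevalence): 0.2222
```

The model scores unseen sequences against known terms at mAP 0.62, and —
the point of the architecture — scores the six terms it never trained on at
mAP 0.53, 2.4× the chance floor and above the description-similarity
baseline (0.44), purely by composing the motif vocabulary shared between
unseen and training descriptions. `clf.predict_proba(proteins, terms)`
returns per-pair probabilities for any term catalog, including EC numbers
wrapped via `funcmatch.inference_eval.ec_to_term`.

The same pipeline is scriptable from the shell:

```bash
funcmatch simulate --config world.yaml --out data/
funcmatch train    --config run.yaml
funcmatch predict  --checkpoint model.npz --sequences data/test.fasta \
                   --terms data/terms.tsv --out scores.tsv
funcmatch evaluate --scores scores.tsv --truth-sequences data/test.fasta \
                   --truth-annotations data/test_annotations.tsv \
                   --terms data/terms.tsv --by namespace
```

## Layout

| module | contents |
|---|---|
| `funcmatch.data_io` | domain types; FASTA / annotation-TSV / term-catalog (TSV + OBO subset) / embedding-table readers and writers; dataset cleaning |
| `funcmatch.ontology` | DAG reasoning: ancestor propagation, term frequencies, leaf/inferred classification, zero-shot split construction |
| `funcmatch.encoders` | frozen-encoder contract: deterministic toy k-mer / token encoders, table lookup |
| `funcmatch.model_core` | the pair-scoring network, focal loss, checkpoints |
| `funcmatch.training` | weighted sampling, augmentations, Adam + clipping, the training loop |
| `funcmatch.estimator` | `ProteinFunctionClassifier`, the scikit-learn-style front door |
| `funcmatch.inference_eval` | ensembled prediction, EC descriptions, similarity baseline, mAP metrics, concordance |
| `funcmatch.synthetic_data` | the motif-world generator and dataset statistics |
| `funcmatch.cli` | `funcmatch` command-line entry point |
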