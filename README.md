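# rnamod

Interpretable multi-scale k-mer transformer models for RNA-modification site
prediction.

Post-transcriptional RNA modifications — N1-methyladenosine (m1A),
N6-methyladenosine (m6A), pseudouridine (Ψ) — are laid down at sites whose
local sequence context carries a learnable "grammar". `rnamod` is a toolkit
for learning that grammar from labeled sequence windows and, crucially, for
reading it back out of the trained model: it predicts whether the centered
nucleotide of a window is modified, and explains the prediction through the
encoder's attention weights, harvested motifs and substrate enrichment
statistics. It is aimed at computational epigenomics practitioners who want a
fully inspectable, CPU-sized implementation of the language-model approach to
site prediction, validated end-to-end on synthetic planted-motif benchmarks.

## The model

A sequence window is tokenized into overlapping k-mers (k ∈ {3..6}, stride 1;
a length-L window yields L − k + 1 tokens, framed as
`[CLS] t₁ … t_{L−k+1} [SEP]`, vocabulary size 4ᵏ + 5). A bidirectional
transformer encoder (12-layer full preset, or a 2-layer / 64-hidden / 4-head
tiny preset that trains in seconds on one CPU core) produces a pooled
representation h. Two tokenization scales are combined by a learned **fusion
gate**

    F   = σ(W₁ h_kmer₁ + W₂ h_kmer₂)
    h_M = F ⊙ h_kmer₁ + (1 − F) ⊙ h_kmer₂

so every fused component is a convex combination of the two scales. A
logistic head maps h (or h_M) to the modification probability p, trained with
binary cross-entropy

    L_CE = −y log p − (1 − y) log(1 − p)

regularized by **FGM adversarial training**: each step perturbs the token
embeddings by r_adv = ξ g/‖g‖₂ (g the loss gradient at the embedding output,
‖r_adv‖₂ = ξ) and takes one optimizer step on the accumulated clean +
perturbed gradients. Evaluation reports Sn, Sp, Acc, MCC and rank-based AUC,
with five-fold stratified cross-validation and train-on-one /
test-on-another transfer matrices across datasets.

The deep-learning stack (transformer, autodiff, Adam, FGM) is implemented on
NumPy in-package — models here are deliberately small enough that a compact
reverse-mode engine is the whole dependency story.

## Worked example

```python
from rnamod import SyntheticSpec, generate, KmerTransformerClassifier, roc_auc
from sklearn.model_selection import train_test_split

spec = SyntheticSpec(n_pos=200, n_neg=200, motif="U.AAU", seed=7)
dataset, truth = generate(spec)          # 41-nt windows, motif near center
X, y = dataset.sequences(), dataset.labels()
Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.2, stratify=y,
                                      random_state=0)

clf = KmerTransformerClassifier(kmers=(5,), random_state=7)
clf.fit(Xtr, ytr)
print(f"held-out AUC: {roc_auc(yte, clf.predict_proba(Xte)[:, 1]):.3f}")
```

prints

```
held-out AUC: 0.926
```

meaning the tiny encoder separates motif-bearing from background windows with
92.6% probability of ranking a random positive above a random negative.
The same model's attention profiles localize the planted motif: on held-out
positives the mean normalized attention over the four motif literals is
≈ 0.80 versus ≈ 0.20 elsewhere, the harvested position-frequency matrix has
consensus `UAAAU` (matching the motif at every non-wildcard column), and the
substrate scan ranks `U.AAU` first.

The same workflow is scriptable from the shell:

```sh
rnamod simulate --n-pos 200 --n-neg 200 --seed 7 --out-dir runs/sim
rnamod train --fasta runs/sim/synthetic.fasta \
             --labels runs/sim/synthetic.labels.tsv \
             --kmers 5 --seed 7 --out-dir runs/train
rnamod interpret --model-dir runs/train \
                 --fasta runs/sim/synthetic.fasta \
                 --labels runs/sim/synthetic.labels.tsv
```

`train --kmers 3,5` engages the fusion gate; `interpret` writes the attention
heatmap CSV, a MEME-minimal motif file (TOMTOM-compatible) and the substrate
table.

## Layout

| module | contents |
| --- | --- |
| `rnamod.io` | FASTA + label-table reading, class-ratio policy, stratified folds |
| `rnamod.tokenization` | k-mer vocabularies, token-stream encoding, scale pairs |
| `rnamod.autodiff` | minimal reverse-mode tensor engine |
| `rnamod.model` | transformer encoder, fusion gate, heads, checkpointing |
| `rnamod.training` | BCE, FGM, adversarial loop, cross-validated `train()` |
| `rnamod.estimator` | scikit-learn `KmerTransformerClassifier` |
| `rnamod.evaluation` | confusion metrics, MCC, AUC, cross-species matrices |
| `rnamod.interpretation` | attention profiles, motif harvest, MEME export, substrate scan |
| `rnamod.synthetic` | planted-motif dataset generator |
| `rnamod.cli` | `rnamod` console script |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
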