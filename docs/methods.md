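# Methods

This note documents the models and procedures implemented in `rnamod`, the
defaults they ship with, and what the synthetic validation does and does not
establish.

## Problem setting

The unit of analysis is a short RNA sequence window (default 41 nt) centered
on a candidate modified nucleotide, labeled positive if the center carries
the modification (m1A, m6A, pseudouridine, …) and negative otherwise.
Windows are assumed pre-extracted and homology-reduced upstream; the package
takes FASTA plus a two-column id/label table. Internally all sequences are
mapped to the DNA alphabet (U → T) so the same tokenizer serves RNA and DNA
input; interpretation outputs convert back to RNA.

## Tokenization

A window of length L yields L − k + 1 overlapping k-mers (stride 1), one
token each, with k ∈ {3, 4, 5, 6}. The scale-k vocabulary is the 4ᵏ k-mers
in lexicographic order plus five special tokens in a fixed reserved block:
`[PAD]`=0, `[UNK]`=1, `[CLS]`=2, `[SEP]`=3, `[MASK]`=4. Padding at id 0 makes
the attention mask equal to the nonzero-id indicator for clean input. Streams
are framed `[CLS] … [SEP]` and padded to a fixed length; a stream that would
overflow is an error by default, with opt-in center-preserving truncation
around the candidate site (silent truncation would quietly break the
centered-site assumption). k-mers containing any character outside
{A,C,G,T} map to `[UNK]`; IUPAC ambiguity codes are rejected unless the
permissive mode maps them to an `[UNK]`-producing `N`.

## Encoder

A standard post-norm bidirectional transformer: token + learned positional
embeddings with layer norm, then per layer multi-head self-attention →
add & norm → GELU feed-forward → add & norm. Two presets:

| preset | layers | hidden | heads | FFN | dropout |
| --- | --- | --- | --- | --- | --- |
| `full` | 12 | 768 | 12 | 3072 | 0.1 |
| `tiny` | 2 | 64 | 4 | 128 | 0.0 |

The full preset mirrors the canonical 12-layer geometry used by pretrained
genomic language models; an import hook (`SequenceClassifier.load`) accepts
externally supplied checkpoints with a matching config, but no pretrained
weights ship with the package. The tiny preset is the workhorse: it trains
from scratch in tens of seconds on one CPU core, which is what makes the
planted-motif validation and the test suite tractable. The sequence summary
is the `[CLS]` representation by default (mask-weighted mean pooling is
available); with dropout at 0 every forward pass is bit-reproducible.

The model layer is written against an in-package reverse-mode autodiff
engine over NumPy float64 arrays (`rnamod.autodiff`). Models at this scale
spend their time in a handful of dense matmuls, so a ~300-line tensor engine
with exact gradients (verified against central differences in the test
suite) keeps the whole stack inspectable and the dependency surface minimal.

An optional masked-language-model head supports small-scale pretraining:
15% of non-special tokens are selected per sequence (at least one is always
forced), with the standard 80/10/10 mask/random/keep replacement, and the
loss is the cross-entropy over masked positions.

## Fusion gate

Two tokenizations of the same window (an ordered scale pair, e.g. (3, 5))
are encoded — through one shared-weight encoder by default, per-scale
encoders optionally — and their pooled vectors h₁, h₂ blended as

    F = σ(W₁h₁ + W₂h₂),  h_M = F ⊙ h₁ + (1 − F) ⊙ h₂.

W₁, W₂ are full linear maps producing a vector gate; a config switch
collapses them to a single scalar logit. The vector gate strictly
generalizes the scalar one and matches common gated-fusion practice. Each
fused component is a convex combination of the two scale representations
(min ≤ h_M ≤ max elementwise), which the tests assert over random triples.
Sharing the encoder across scales keeps the tiny preset trainable on small
data; the asymmetry of the pair order (F weights the first scale) is
preserved end to end.

## Adversarial training (FGM)

Each optimizer step: (1) clean forward/backward giving loss L_CE and the
gradient g of L_CE at the token-embedding output; (2) perturbation
r_adv = ξ g/‖g‖₂ added to the embedding output (never written into the
embedding table); (3) forward/backward on the perturbed batch; (4) one Adam
step on the accumulated gradients of both passes. The per-epoch adversarial
objective is the mean perturbed-batch cross-entropy over the epoch's N
batches, reported as a nonnegative loss. With FGM disabled the step is
exactly plain cross-entropy training (asserted bitwise in the tests).

Sign convention: the perturbation defaults to the loss-*ascent* direction,
the worst-case input shift that adversarial training is meant to defend
against; an `fgm_ascent=False` switch provides the descent-direction
variant for comparison. A zero gradient has no direction; the perturbation
is then zero (logged).

ξ defaults to **0.1** in embedding-L2 units. This was calibrated on the
synthetic benchmark: with the tiny preset trained from scratch, normalized
perturbations of magnitude ≳ 0.3 overwhelm the (initially small) gradient
signal and force the model to the constant-½ solution, while ξ ≈ 0.1
regularizes without destroying learning. Sweeps over
{0.01, 0.05, 0.1, 0.3, 0.5, 1.0} are exposed via config.

Optimization: Adam at peak learning rate 3e-3 with linear warmup over the
first 10% of steps and cosine decay to 10% of peak — the standard recipe for
post-norm transformer stacks, which stall or diverge at a flat rate when
trained from scratch. Defaults: 30 epochs, batch 16. All randomness
(initialization, batch order, masking) flows from one integer seed.

## Data policy and evaluation

Training sets whose negative:positive ratio exceeds 10:1 are randomly
under-sampled (seeded, without replacement) to a target ratio, default 1:1;
positives are never dropped and evaluation sets are never re-balanced — test
imbalance is part of what the metrics should reflect. Cross-validation uses
stratified folds whose per-class sizes differ by at most one.

Threshold metrics (Sn, Sp, Acc, MCC) derive from confusion counts at a
configurable threshold (default 0.5, ties predict positive). A missing class
makes Sn or Sp undefined and is reported as NaN, never silently 0; a zero
factor in the MCC denominator yields MCC = 0 by the usual convention. AUC is
computed rank-based (Mann-Whitney, ties ½), which is exact and equals the
trapezoidal ROC area; the tests cross-check it against an O(n²) concordance
oracle and scikit-learn.

Cross-species evaluation fits one model per training dataset and scores
every test dataset; a dataset evaluated against its own model uses a
held-out split, never training records, and single-class cells are recorded
as missing rather than 0. The matrix is exported with training datasets on
the x-axis and testing datasets on the y-axis.

## Interpretation

Per-token importance is read from the encoder's self-attention: by default
the attention the `[CLS]` position pays to each k-mer token in the final
layer, averaged over heads (layer, head, and mean-over-layers policies are
selectable and recorded in output metadata). Token scores are mapped to
nucleotide positions — position i inherits the mean score of every k-window
covering it — and min-max normalized per sequence (a numerically constant
profile maps to all-ones; an all-zero profile stays zero). For a scale pair,
per-scale normalized profiles are averaged position-wise and re-normalized.

Motif harvest takes, per sequence, the length-w window (w odd, default 5)
maximizing the summed position scores, keeps it if its peak exceeds the
sequence's q-quantile (default 0.75), and stacks the kept windows into a
position frequency matrix exportable as MEME minimal text (TOMTOM's input
format; round-trip parsing is tested to 1e-6).

The substrate scan is a motif-x-style over-representation test: all
width-w wildcard patterns with at most `max_wildcards` dots, anchored within
±w of the candidate site, are counted at the sequence level in positives and
background, scored by a one-sided binomial test of the positive match count
against the add-½-smoothed background rate, Bonferroni-corrected over the
full enumerable pattern space, and greedily de-duplicated (a pattern
subsumed by a higher-ranked generalization or refinement is dropped). The
iterative residual refinement of the original motif-x is approximated by
this single-pass ranking, not replicated exactly.

## Synthetic benchmark

The generator emulates a site-prediction dataset with a known answer:
negatives are i.i.d. draws from a base composition (default uniform);
positives additionally have the non-wildcard bases of a wildcard motif
(default `U.AAU`, the pattern used throughout the validation; `C.GU.` serves
as the divergent second motif) written at an offset jittered uniformly
within ±3 nt of the window center, with probability `plant_prob`. Wildcard
positions remain background draws and are not forced away from the
consensus. Planting positions are written to a sidecar table, never to FASTA
headers, so models cannot see them. Pseudo-species families share or differ
in motif to emulate within- versus across-taxonomy conservation.

What passing the synthetic validation shows: the full pipeline — k-mer
tokenization, transformer encoding, FGM-regularized training, attention
read-out, motif harvest, substrate enrichment, transfer evaluation —
recovers a deterministic, localized, literal sequence signal from realistic
sample sizes (400 windows), and collapses to chance when the signal is
absent. What it does not show: performance on real transcriptomic data,
whose signals are degenerate, context-dependent, structure-mediated and
entangled with composition biases none of which the generator simulates.

## Validation experiment sizes

The packaged experiments (tests and `scripts/acceptance.py`) use the
generator defaults — 200 positives + 200 negatives per dataset, 41-nt
windows — with five-fold cross-validation at scale k = 5 and a 3×3
pseudo-species matrix. Scale k = 5 is used for the validation study because
it matches the planted motif's width: a single token then spans the whole
motif, so classification and attention localization probe the same tokens
and the harvested windows align with the motif start. (k = 3 classifies
equally well but concentrates attention on the motif's trailing trinucleotide,
shifting harvested windows.) At these sizes one cross-validated training run
takes a few minutes on a single CPU core.

## Known limitations

- No pretrained genomic language model is bundled; from-scratch tiny-preset
  training is what the validation exercises. The full preset is instantiable
  and checkpoint-loadable but not trained in-package at scale.
- The NumPy engine is single-threaded per op and float64; it is sized for
  desk-scale experiments, not genome-scale corpora.
- FGM is the only adversary implemented (no multi-step PGD, no virtual
  adversarial training).
- The substrate scan's binomial + Bonferroni ranking approximates motif-x
  rather than reproducing its iterative chi-square refinement.
- Attention is an importance *proxy*; the validation shows it localizes a
  planted literal signal, not that it constitutes a causal explanation.
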