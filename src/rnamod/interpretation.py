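"""Attention-based interpretation: position scores, motif harvest, enrichment.

The trained encoder's self-attention provides a per-token importance proxy:
by default the attention the [CLS] position pays to each k-mer token in the
final layer, averaged over heads. Token scores are spread back onto
nucleotide positions (a position inherits the mean score of every k-mer
window covering it) and min-max normalized per sequence. High-attention
windows are stacked into a position frequency matrix, exportable as MEME
minimal text, and a motif-x-style scan ranks wildcard substrate patterns by
one-sided binomial over-representation in positives versus background.

Motif outputs use the RNA alphabet (U, not T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy.stats import binom

from .io import SequenceRecord, dna_to_rna_alphabet
from .model import SequenceClassifier
from .tokenization import TokenizedSequence, encode_tokens

__all__ = [
    "AttentionProfile",
    "PositionFrequencyMatrix",
    "SubstratePattern",
    "extract_token_attention",
    "token_to_position_scores",
    "attention_profile",
    "harvest_motif",
    "export_meme_minimal",
    "parse_meme_minimal",
    "substrate_scan",
]

_RNA = "ACGU"


@dataclass
class AttentionProfile:
    """Normalized per-token and per-nucleotide importance for one sequence."""

    sequence_id: str
    k: object  # int or (k1, k2) scale pair
    token_scores: np.ndarray
    position_scores: np.ndarray  # min-max normalized, length L
    normalization: str = "minmax"


@dataclass
class PositionFrequencyMatrix:
    """4 x w base counts over {A,C,G,U} from stacked motif windows."""

    counts: np.ndarray  # shape (4, w)
    n_windows: int

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        return "".join(_RNA[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class SubstratePattern:
    """Wildcard pattern over {A,C,G,U,.} with enrichment evidence."""

    pattern: str
    pos_count: int
    bg_count: int
    p_value: float
    corrected_p: float


def extract_token_attention(
    model_or_attentions,
    tokens: TokenizedSequence,
    layer: int = -1,
    head: object = "mean",
) -> np.ndarray:
    """Importance score per k-mer token: [CLS]-row attention.

    ``layer`` indexes encoder layers (default: last); ``head`` is an index,
    ``"mean"`` over heads, or ``"mean_layers"`` to also average over layers.
    Special tokens ([CLS]/[SEP]/[PAD]) are excluded: the returned vector has
    one entry per k-mer, a sub-row of a softmax row (nonnegative, sum <= 1).
    """
    if isinstance(model_or_attentions, SequenceClassifier):
        enc = model_or_attentions.encoder_for(0)
        attentions = enc.encode(tokens).attentions
    elif hasattr(model_or_attentions, "encode"):
        attentions = model_or_attentions.encode(tokens).attentions
    else:
        attentions = list(model_or_attentions)
    n_layers = len(attentions)
    n_heads = attentions[0].shape[0]
    if head == "mean_layers":
        mat = np.mean([a.mean(axis=0) for a in attentions], axis=0)
    else:
        if not -n_layers <= layer < n_layers:
            raise IndexError(f"layer {layer} out of range for {n_layers} layers")
        a = attentions[layer]
        if head == "mean":
            mat = a.mean(axis=0)
        else:
            if not -n_heads <= int(head) < n_heads:
                raise IndexError(f"head {head} out of range for {n_heads} heads")
            mat = a[int(head)]
    cls_row = mat[0]  # attention paid by [CLS]
    return cls_row[1 : 1 + tokens.n_kmers].copy()


def token_to_position_scores(token_scores: np.ndarray, k: int, L: int) -> np.ndarray:
    """Spread token scores onto nucleotide positions; min-max normalize.

    Position i receives the mean score of the tokens whose k-window covers it
    (token indices max(0, i-k+1) .. min(i, L-k)). Uniform nonzero scores map
    to all-ones; an all-zero profile stays zero.
    """
    token_scores = np.asarray(token_scores, dtype=float)
    n_tokens = L - k + 1
    if token_scores.shape[0] != n_tokens:
        raise ValueError(
            f"expected {n_tokens} token scores for L={L}, k={k}; "
            f"got {token_scores.shape[0]}"
        )
    raw = np.empty(L)
    for i in range(L):
        lo = max(0, i - k + 1)
        hi = min(i, L - k)
        raw[i] = token_scores[lo : hi + 1].mean()
    return _minmax(raw)


def _minmax(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize; a (numerically) constant profile maps to all-ones
    (or stays zero if it is all-zero)."""
    span = raw.max() - raw.min()
    if span > 1e-9 * max(abs(raw.max()), 1e-30):
        return (raw - raw.min()) / span
    if raw.max() > 0:
        return np.ones_like(raw)
    return np.zeros_like(raw)


def attention_profile(
    model: SequenceClassifier,
    record: SequenceRecord,
    kmers,
    max_len: int = 64,
    vocabs=None,
    layer: int = -1,
    head: object = "mean",
) -> AttentionProfile:
    """End-to-end per-nucleotide attention profile for one record.

    For a scale pair, the per-scale normalized position scores are averaged
    position-wise (and the result re-normalized), giving one combined profile
    per sequence.
    """
    from .tokenization import build_vocab

    kmers = tuple(kmers)
    vocabs = vocabs or {k: build_vocab(k) for k in kmers}
    max_len = min(max_len, model.config.max_tokens)
    L = len(record.sequence)
    per_scale, token_scores = [], []
    for i, k in enumerate(kmers):
        toks = encode_tokens(record.sequence, vocabs[k], max_len=max_len)
        enc = model.encoder_for(i)
        scores = extract_token_attention(enc, toks, layer=layer, head=head)
        token_scores.append(scores)
        per_scale.append(token_to_position_scores(scores, k, L))
    combined = _minmax(np.mean(per_scale, axis=0))
    return AttentionProfile(
        sequence_id=record.id,
        k=kmers[0] if len(kmers) == 1 else kmers,
        token_scores=token_scores[0] if len(kmers) == 1 else np.array(token_scores, dtype=object),
        position_scores=combined,
    )


def harvest_motif(
    sequences: list[str],
    profiles: list[AttentionProfile],
    width: int = 5,
    quantile: float = 0.75,
) -> PositionFrequencyMatrix:
    """Stack each sequence's top-attention window into a PFM.

    Per sequence, the length-``width`` window maximizing the summed position
    scores is taken; it contributes to the PFM only if its peak score exceeds
    the ``quantile`` of that sequence's scores.
    """
    if width % 2 == 0:
        raise ValueError("width must be odd")
    counts = np.zeros((4, width))
    n_windows = 0
    base_index = {b: i for i, b in enumerate(_RNA)}
    for seq, prof in zip(sequences, profiles):
        seq_rna = dna_to_rna_alphabet(seq)
        L = len(seq_rna)
        if width > L:
            raise ValueError(f"window width {width} exceeds sequence length {L}")
        s = prof.position_scores
        sums = np.array([s[i : i + width].sum() for i in range(L - width + 1)])
        start = int(sums.argmax())
        window = s[start : start + width]
        if window.max() <= np.quantile(s, quantile):
            continue
        for j, base in enumerate(seq_rna[start : start + width]):
            counts[base_index[base], j] += 1
        n_windows += 1
    return PositionFrequencyMatrix(counts=counts, n_windows=n_windows)


def export_meme_minimal(
    pfm: PositionFrequencyMatrix,
    motif_name: str = "attention_motif",
    alphabet: str = "ACGU",
    background=None,
) -> str:
    """Serialize a PFM as MEME minimal motif format text."""
    if pfm.n_windows == 0:
        raise ValueError("cannot export a PFM built from zero windows")
    background = background or [0.25, 0.25, 0.25, 0.25]
    probs = pfm.probabilities()
    lines = [
        "MEME version 4",
        "",
        f"ALPHABET= {alphabet}",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(alphabet, background)),
        "",
        f"MOTIF {motif_name}",
        f"letter-probability matrix: alength= {len(alphabet)} w= {pfm.width} "
        f"nsites= {pfm.n_windows}",
    ]
    for col in range(pfm.width):
        lines.append(" ".join(f"{probs[row, col]:.6f}" for row in range(4)))
    lines.append("")
    return "\n".join(lines)


def parse_meme_minimal(text: str) -> np.ndarray:
    """Parse the letter-probability matrix back out of MEME minimal text."""
    lines = text.splitlines()
    if not any(line.startswith("MEME version") for line in lines):
        raise ValueError("not MEME minimal format: missing version line")
    it = iter(lines)
    for line in it:
        if line.startswith("letter-probability matrix"):
            w = int(line.split("w=")[1].split()[0])
            break
    else:
        raise ValueError("no letter-probability matrix found")
    rows = [next(it).split() for _ in range(w)]
    return np.array(rows, dtype=float).T  # back to (4, w)


def _pattern_generalizations(word: str, max_wildcards: int):
    """All wildcard patterns (with <= max_wildcards dots) matching ``word``."""
    n = len(word)
    for n_wild in range(0, max_wildcards + 1):
        if n_wild >= n:
            continue
        for dots in combinations(range(n), n_wild):
            chars = list(word)
            for d in dots:
                chars[d] = "."
            yield "".join(chars)


def _count_matches(sequences, sites, width: int, max_wildcards: int):
    """Per-pattern count of sequences matched near their candidate site.

    A sequence matches a pattern if the pattern occurs verbatim at any start
    offset within +/-``width`` of the site-centered start. Counting is done by
    enumerating the wildcard generalizations of each observed window, which is
    equivalent to exact matching of every enumerable pattern.
    """
    counts: dict[str, int] = {}
    for seq, site in zip(sequences, sites):
        seq_rna = dna_to_rna_alphabet(seq)
        center_start = site - width // 2
        seen: set[str] = set()
        for start in range(center_start - width, center_start + width + 1):
            if start < 0 or start + width > len(seq_rna):
                continue
            word = seq_rna[start : start + width]
            for pat in _pattern_generalizations(word, max_wildcards):
                seen.add(pat)
        for pat in seen:
            counts[pat] = counts.get(pat, 0) + 1
    return counts


def _subsumes(a: str, b: str) -> bool:
    """True if one pattern refines the other (same width, compatible bases)."""
    return all(x == "." or x == y for x, y in zip(a, b)) or all(
        y == "." or x == y for x, y in zip(a, b)
    )


def substrate_scan(
    positives: list[SequenceRecord],
    background: list[SequenceRecord],
    width: int = 5,
    max_wildcards: int = 2,
    min_count: int = 5,
    alpha: float = 0.01,
    top: int = 10,
) -> list[SubstratePattern]:
    """Motif-x-style over-representation scan near the candidate site.

    Enumerates width-length wildcard patterns (<= ``max_wildcards`` dots, at
    least one literal base) anchored within +/-``width`` of each record's
    site, counts sequence-level matches in positives and background, and
    scores each pattern by a one-sided binomial test of the positive match
    count against the (smoothed) background match rate. Bonferroni correction
    runs over the full enumerable pattern space; lower-ranked patterns
    subsumed by a kept one are dropped.
    """
    if not positives or not background:
        raise ValueError("both positive and background sets must be nonempty")
    min_len = min(len(r.sequence) for r in list(positives) + list(background))
    if width > min_len:
        raise ValueError(f"width {width} exceeds shortest sequence ({min_len})")

    pos_counts = _count_matches(
        [r.sequence for r in positives], [r.site for r in positives],
        width, max_wildcards,
    )
    bg_counts = _count_matches(
        [r.sequence for r in background], [r.site for r in background],
        width, max_wildcards,
    )
    n_pos, n_bg = len(positives), len(background)
    # full enumerable pattern space for the Bonferroni factor
    n_tests = sum(
        math.comb(width, w) * 4 ** (width - w) for w in range(0, max_wildcards + 1)
    )

    scored = []
    for pat, c_pos in pos_counts.items():
        if c_pos < min_count:
            continue
        c_bg = bg_counts.get(pat, 0)
        bg_rate = (c_bg + 0.5) / (n_bg + 1.0)  # smoothed background match rate
        p = float(binom.sf(c_pos - 1, n_pos, bg_rate))
        scored.append(
            SubstratePattern(
                pattern=pat,
                pos_count=c_pos,
                bg_count=c_bg,
                p_value=p,
                corrected_p=min(1.0, p * n_tests),
            )
        )
    scored.sort(key=lambda s: (s.p_value, -s.pos_count, s.pattern))

    kept: list[SubstratePattern] = []
    for cand in scored:
        if cand.corrected_p > alpha:
            continue
        if any(_subsumes(kept_pat.pattern, cand.pattern) for kept_pat in kept):
            continue
        kept.append(cand)
        if len(kept) >= top:
            break
    return kept


def substrate_table_tsv(patterns: list[SubstratePattern], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tpattern\tpos_count\tbg_count\tp_value\tcorrected_p\n")
        for i, p in enumerate(patterns, start=1):
            fh.write(
                f"{i}\t{p.pattern}\t{p.pos_count}\t{p.bg_count}\t"
                f"{p.p_value:.3e}\t{p.corrected_p:.3e}\n"
            )
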