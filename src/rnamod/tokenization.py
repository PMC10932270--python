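"""Overlapping k-mer tokenization with BERT-style special-token framing.

A sequence of length L yields L - k + 1 overlapping k-mers (stride 1). The
vocabulary for scale k holds all 4^k k-mers over {A,C,G,T} plus five special
tokens, so |V| = 4^k + 5. Token streams are framed as
``[CLS] kmer_1 ... kmer_{L-k+1} [SEP] [PAD]*`` up to ``max_len``.

RNA input is accepted everywhere: the encoding entry points convert U -> T
before vocabulary lookup, so callers may pass either alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .io import rna_to_dna_alphabet

__all__ = [
    "SPECIAL_TOKENS",
    "PAD_ID",
    "UNK_ID",
    "CLS_ID",
    "SEP_ID",
    "MASK_ID",
    "KmerVocabulary",
    "TokenizedSequence",
    "build_vocab",
    "kmerize",
    "encode_tokens",
    "multiscale_encode",
]

# Fixed reserved block: padding at id 0 simplifies mask construction.
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)

_BASES = "ACGT"
DEFAULT_MAX_LEN = 64


@dataclass(frozen=True)
class KmerVocabulary:
    """Deterministic vocabulary for one k: 5 special tokens + 4^k k-mers."""

    k: int
    token_to_id: dict[str, int]

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for token, idx in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{token}\t{idx}\n")

    @staticmethod
    def from_text(path) -> "KmerVocabulary":
        mapping = {}
        for line in Path(path).read_text().splitlines():
            token, idx = line.split("\t")
            mapping[token] = int(idx)
        k = len(next(t for t in mapping if not t.startswith("[")))
        return KmerVocabulary(k=k, token_to_id=mapping)


@dataclass(frozen=True)
class TokenizedSequence:
    """Token-id stream for one (sequence, k) pair.

    ``ids`` has length ``max_len``; content (``[CLS]`` + k-mers + ``[SEP]``)
    occupies the first ``source_length - k + 3`` positions, the rest is
    ``[PAD]`` with a zero attention mask.
    """

    ids: np.ndarray
    k: int
    source_length: int
    attention_mask: np.ndarray

    @property
    def n_content(self) -> int:
        return self.source_length - self.k + 3

    @property
    def n_kmers(self) -> int:
        return self.source_length - self.k + 1


def build_vocab(k: int) -> KmerVocabulary:
    """Build the deterministic scale-k vocabulary (size 4^k + 5).

    Special tokens occupy ids 0-4; k-mer ids follow in lexicographic order.
    """
    if not 3 <= k <= 6:
        raise ValueError(f"k must be in [3, 6], got {k}")
    mapping = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for i, kmer in enumerate(product(_BASES, repeat=k)):
        mapping["".join(kmer)] = len(SPECIAL_TOKENS) + i
    return KmerVocabulary(k=k, token_to_id=mapping)


def kmerize(sequence: str, k: int) -> list[str]:
    """Slice a sequence into its L - k + 1 overlapping k-mers (stride 1)."""
    L = len(sequence)
    if L < k:
        raise ValueError(f"sequence length {L} shorter than k={k}")
    return [sequence[i : i + k] for i in range(L - k + 1)]


def _truncate_center(sequence: str, site: int, keep: int) -> str:
    start = min(max(0, site - keep // 2), len(sequence) - keep)
    return sequence[start : start + keep]


def encode_tokens(
    sequence: str,
    vocab: KmerVocabulary,
    max_len: int = DEFAULT_MAX_LEN,
    permissive: bool = False,
    truncate: bool = False,
    site_index: int | None = None,
) -> TokenizedSequence:
    """Encode one sequence at scale ``vocab.k`` into a padded id stream.

    U -> T conversion is applied internally. k-mers containing any character
    outside {A,C,G,T} map to ``[UNK]``. A sequence whose content would exceed
    ``max_len`` is a hard error unless ``truncate=True``, which keeps a
    center-preserving window around ``site_index`` (default: sequence center).
    """
    seq = rna_to_dna_alphabet(sequence, permissive=permissive)
    k = vocab.k
    content = len(seq) - k + 3
    if content > max_len:
        if not truncate:
            raise ValueError(
                f"content length {content} exceeds max_len={max_len}; pass "
                "truncate=True for center-preserving truncation or raise max_len"
            )
        keep = max_len - 3 + k
        site = site_index if site_index is not None else len(seq) // 2
        seq = _truncate_center(seq, site, keep)
    kmers = kmerize(seq, k)
    ids = np.full(max_len, PAD_ID, dtype=np.int64)
    ids[0] = CLS_ID
    for i, km in enumerate(kmers):
        ids[1 + i] = vocab[km] if set(km) <= set(_BASES) else UNK_ID
    ids[1 + len(kmers)] = SEP_ID
    mask = np.zeros(max_len, dtype=np.int64)
    mask[: len(kmers) + 2] = 1
    return TokenizedSequence(
        ids=ids, k=k, source_length=len(seq), attention_mask=mask
    )


def multiscale_encode(
    sequence: str,
    k1: int,
    k2: int,
    vocabs: dict[int, KmerVocabulary] | None = None,
    max_len: int = DEFAULT_MAX_LEN,
    **kwargs,
) -> tuple[TokenizedSequence, TokenizedSequence]:
    """Tokenize the same sequence independently at two scales (k1, k2).

    The order of the pair is preserved: the fusion gate treats the two scales
    asymmetrically (gate F weights the first scale, 1 - F the second).
    """
    if k1 == k2:
        raise ValueError("multiscale encoding requires two distinct scales")
    vocabs = vocabs or {}
    out = []
    for k in (k1, k2):
        vocab = vocabs.get(k) or build_vocab(k)
        out.append(encode_tokens(sequence, vocab, max_len=max_len, **kwargs))
    return out[0], out[1]
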