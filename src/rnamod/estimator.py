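"""scikit-learn-compatible estimator wrapping the k-mer transformer pipeline.

``KmerTransformerClassifier`` takes raw RNA (or DNA) sequence strings as X and
binary labels as y, handles tokenization, encoder construction, FGM
adversarial fine-tuning, and exposes ``predict``/``predict_proba``. It clones
and composes like any other sklearn classifier::

    clf = KmerTransformerClassifier(kmers=(3, 5), epochs=30, random_state=7)
    clf.fit(train_sequences, train_labels)
    p = clf.predict_proba(test_sequences)[:, 1]
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import EncoderConfig
from .training import AdversarialConfig, fit_model, predict_proba_model

__all__ = ["KmerTransformerClassifier"]


class KmerTransformerClassifier(BaseEstimator, ClassifierMixin):
    """Transformer classifier over overlapping k-mer tokens.

    Parameters
    ----------
    kmers : tuple of int
        One scale, e.g. ``(3,)``, or an ordered pair, e.g. ``(3, 5)``; a pair
        engages the fusion gate (gate F weights the first scale).
    preset : {"tiny", "full"}
        Encoder geometry. ``tiny`` (2 layers, 64 hidden, 4 heads) trains on a
        single CPU core; ``full`` is the canonical 12-layer geometry.
    epochs, batch_size, learning_rate : training-loop settings (Adam).
    adversarial : bool
        Enable FGM adversarial fine-tuning.
    xi : float
        FGM perturbation magnitude (L2 norm in embedding space).
    fgm_ascent : bool
        Perturb in the loss-ascent (worst-case) direction; set False for the
        descent-direction variant.
    shared_encoder : bool
        Share one encoder across the two scales of a pair.
    scalar_gate : bool
        Collapse the fusion gate to a single scalar per sequence.
    pooling : {"cls", "mean"}
        Sequence summary: the [CLS] vector or a mask-weighted token mean.
    max_len : int
        Token-stream capacity; sequences whose content exceeds it are an error.
    permissive : bool
        Map IUPAC ambiguity codes to [UNK] instead of rejecting them.
    random_state : int
        Seed for all randomness (init, batching, FGM bookkeeping).

    Attributes
    ----------
    model_ : SequenceClassifier
        The fitted encoder/gate/head stack.
    vocabs_ : dict[int, KmerVocabulary]
        Per-scale vocabularies.
    history_ : dict[str, list[float]]
        Per-epoch mean clean and adversarial losses.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        kmers=(3,),
        preset: str = "tiny",
        epochs: int = 30,
        batch_size: int = 16,
        learning_rate: float = 3e-3,
        adversarial: bool = True,
        xi: float = 0.1,
        fgm_ascent: bool = True,
        shared_encoder: bool = True,
        scalar_gate: bool = False,
        pooling: str = "cls",
        max_len: int = 64,
        permissive: bool = False,
        random_state: int = 0,
    ):
        self.kmers = kmers
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.adversarial = adversarial
        self.xi = xi
        self.fgm_ascent = fgm_ascent
        self.shared_encoder = shared_encoder
        self.scalar_gate = scalar_gate
        self.pooling = pooling
        self.max_len = max_len
        self.permissive = permissive
        self.random_state = random_state

    def _sequences(self, X) -> list[str]:
        if isinstance(X, str):
            raise ValueError("X must be a sequence of strings, not a single string")
        seqs = [str(s) for s in X]
        if not seqs:
            raise ValueError("X is empty")
        return seqs

    def _encoder_config(self) -> EncoderConfig:
        from .tokenization import build_vocab

        vocab_size = max(len(build_vocab(k)) for k in self.kmers)
        if self.preset == "tiny":
            return EncoderConfig.tiny(vocab_size=vocab_size, max_tokens=self.max_len)
        if self.preset == "full":
            return EncoderConfig(
                vocab_size=vocab_size,
                max_tokens=max(self.max_len, 512),
                preset="full",
            )
        raise ValueError(f"unknown preset {self.preset!r}")

    def fit(self, X, y):
        seqs = self._sequences(X)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != len(seqs):
            raise ValueError("X and y differ in length")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        adv = AdversarialConfig(
            xi=self.xi,
            enabled=self.adversarial,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
            fgm_ascent=self.fgm_ascent,
        )
        self.model_, self.vocabs_, self.history_ = fit_model(
            seqs,
            y,
            kmers=tuple(self.kmers),
            encoder_config=self._encoder_config(),
            adv=adv,
            max_len=self.max_len,
            shared_encoder=self.shared_encoder,
            scalar_gate=self.scalar_gate,
            pooling=self.pooling,
            permissive=self.permissive,
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        p = predict_proba_model(
            self.model_,
            self.vocabs_,
            self._sequences(X),
            tuple(self.kmers),
            max_len=self.max_len,
            permissive=self.permissive,
        )
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
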