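"""Adversarially regularized training: cross-entropy + FGM perturbations.

Each optimizer step performs (when adversarial training is enabled):

1. a clean forward/backward pass, giving the cross-entropy loss L_CE and the
   gradient g of L_CE with respect to the token-embedding output s;
2. the fast-gradient-method perturbation ``r_adv = xi * g / ||g||_2`` (the
   loss-ascent direction; ``||r_adv||_2 = xi``) added to the embeddings;
3. a second forward/backward pass on the perturbed batch;
4. a single Adam update from the accumulated gradients of both passes.

The per-epoch adversarial objective is the mean of the perturbed-batch
cross-entropies over the N batches of the epoch. With adversarial training
disabled the step reduces exactly to plain cross-entropy fine-tuning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .io import Dataset, FoldAssignment
from .model import EncoderConfig, SequenceClassifier
from .tokenization import DEFAULT_MAX_LEN, build_vocab, encode_tokens

logger = logging.getLogger(__name__)

__all__ = [
    "AdversarialConfig",
    "TrainReport",
    "Adam",
    "binary_cross_entropy",
    "bce_loss",
    "fgm_perturbation",
    "adversarial_step",
    "adversarial_epoch_loss",
    "encode_batch",
    "fit_model",
    "train",
]

_EPS = 1e-7


@dataclass(frozen=True)
class AdversarialConfig:
    """Settings for FGM adversarial fine-tuning.

    ``xi`` is the perturbation magnitude in embedding-norm units;
    ``fgm_ascent=False`` flips the perturbation from the default loss-ascent
    (worst-case) direction to the descent direction.
    """

    xi: float = 0.1
    enabled: bool = True
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 3e-3
    seed: int = 0
    fgm_ascent: bool = True

    def __post_init__(self):
        if self.enabled and self.xi <= 0:
            raise ValueError("xi must be > 0 when adversarial training is enabled")


@dataclass
class TrainReport:
    """Per-fold, per-epoch training losses and validation metrics."""

    clean_loss: dict[int, list[float]] = field(default_factory=dict)
    adv_loss: dict[int, list[float]] = field(default_factory=dict)
    fold_metrics: dict[int, dict[str, float]] = field(default_factory=dict)
    n_batches: int = 0

    def mean_metric(self, key: str) -> float:
        vals = [m[key] for m in self.fold_metrics.values() if not np.isnan(m[key])]
        return float(np.mean(vals)) if vals else float("nan")

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold", "epoch", "clean_loss", "adv_loss"])
            for fold, losses in self.clean_loss.items():
                adv = self.adv_loss.get(fold, [float("nan")] * len(losses))
                for epoch, (c, a) in enumerate(zip(losses, adv)):
                    writer.writerow([fold, epoch, f"{c:.6f}", f"{a:.6f}"])
            writer.writerow([])
            if self.fold_metrics:
                keys = sorted(next(iter(self.fold_metrics.values())))
                writer.writerow(["fold"] + keys)
                for fold, m in sorted(self.fold_metrics.items()):
                    writer.writerow([fold] + [f"{m[k]:.6f}" for k in keys])


class Adam:
    """Adam optimizer over a list of autodiff Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * p.grad ** 2
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps
            )


def binary_cross_entropy(p, y):
    """Elementwise binary cross-entropy -y log p - (1-y) log(1-p).

    Probabilities outside (0, 1) are clamped to [eps, 1-eps] with a warning.
    Accepts scalars or arrays; returns the same shape.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        warnings.warn("probability outside (0,1) clamped for cross-entropy",
                      RuntimeWarning, stacklevel=2)
        p = np.clip(p, _EPS, 1.0 - _EPS)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def bce_loss(p: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy as an autodiff Tensor (stable via epsilon)."""
    y = np.asarray(y, dtype=float)
    return -(
        Tensor(y) * (p + _EPS).log() + Tensor(1.0 - y) * (1.0 - p + _EPS).log()
    ).mean()


def fgm_perturbation(g: np.ndarray, xi: float, ascent: bool = True) -> np.ndarray:
    """Fast-gradient-method perturbation of L2 magnitude ``xi``.

    Default is the loss-ascent direction ``+xi g/||g||_2`` (worst-case input
    shift); ``ascent=False`` gives the descent direction ``-xi g/||g||_2``.
    A zero gradient has no direction: the perturbation is zero (warned).
    """
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient contains non-finite values")
    norm = np.linalg.norm(g)
    if norm == 0.0:
        logger.warning("zero gradient: FGM perturbation undefined, returning 0")
        return np.zeros_like(g)
    sign = 1.0 if ascent else -1.0
    return sign * xi * g / norm


def adversarial_epoch_loss(per_batch_losses) -> float:
    """Epoch-level adversarial objective: mean of per-batch losses."""
    losses = list(per_batch_losses)
    if not losses:
        raise ValueError("adversarial_epoch_loss requires at least one batch loss")
    return float(np.mean(losses))


def adversarial_step(
    model: SequenceClassifier,
    batches: list[tuple[np.ndarray, np.ndarray]],
    y: np.ndarray,
    optimizer: Adam,
    adv: AdversarialConfig,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """One optimizer step; returns (clean_loss, adversarial_loss).

    With ``adv.enabled`` false this is exactly one plain cross-entropy
    forward/backward/update, and the adversarial loss equals the clean loss.
    After the step the embedding table holds its unperturbed values: the
    perturbation only ever enters as an additive constant on the embedding
    *output*, never as a write to the table.
    """
    optimizer.zero_grad()
    p, embs, _ = model.forward(
        batches, retain_embedding_grad=adv.enabled, dropout_rng=dropout_rng
    )
    loss = bce_loss(p, y)
    if not np.isfinite(loss.data):
        raise RuntimeError("non-finite clean loss")
    loss.backward()
    if not adv.enabled:
        optimizer.step()
        return float(loss.data), float(loss.data)

    perturbations = [
        fgm_perturbation(e.grad, adv.xi, ascent=adv.fgm_ascent)
        for e in embs
    ]
    p2, _, _ = model.forward(
        batches, perturbations=perturbations, dropout_rng=dropout_rng
    )
    adv_loss = bce_loss(p2, y)
    if not np.isfinite(adv_loss.data):
        raise RuntimeError("non-finite adversarial loss")
    adv_loss.backward()  # accumulates onto the clean gradients
    optimizer.step()
    return float(loss.data), float(adv_loss.data)


def encode_batch(
    sequences,
    kmers,
    vocabs,
    max_len: int = DEFAULT_MAX_LEN,
    permissive: bool = False,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Tokenize sequences at each scale into (ids, mask) matrices."""
    out = []
    for k in kmers:
        toks = [
            encode_tokens(s, vocabs[k], max_len=max_len, permissive=permissive)
            for s in sequences
        ]
        out.append(
            (np.stack([t.ids for t in toks]), np.stack([t.attention_mask for t in toks]))
        )
    return out


def fit_model(
    sequences,
    labels,
    kmers=(3,),
    encoder_config: EncoderConfig | None = None,
    adv: AdversarialConfig | None = None,
    max_len: int = DEFAULT_MAX_LEN,
    shared_encoder: bool = True,
    scalar_gate: bool = False,
    pooling: str = "cls",
    permissive: bool = False,
    verbose: bool = False,
):
    """Train one classifier on (sequences, labels); fully seeded.

    Returns ``(model, vocabs, history)`` where history maps
    ``clean_loss``/``adv_loss`` to per-epoch lists.
    """
    kmers = tuple(kmers)
    if len(kmers) not in (1, 2):
        raise ValueError("kmers must name one scale or an ordered pair")
    if len(kmers) == 2 and kmers[0] == kmers[1]:
        raise ValueError("scale pair must use two distinct k values")
    adv = adv or AdversarialConfig()
    vocabs = {k: build_vocab(k) for k in kmers}
    # shrink padding to the longest content stream (saves quadratic attention cost)
    max_content = max(len(s) - k + 3 for s in sequences for k in kmers)
    eff_len = min(max_len, max_content)
    if encoder_config is None:
        encoder_config = EncoderConfig.tiny(
            vocab_size=max(len(v) for v in vocabs.values()), max_tokens=eff_len
        )
    eff_len = min(eff_len, encoder_config.max_tokens)
    if max_content > encoder_config.max_tokens:
        raise ValueError(
            f"content length {max_content} exceeds encoder capacity "
            f"{encoder_config.max_tokens}"
        )
    y = np.asarray(labels, dtype=float)
    batches_all = encode_batch(sequences, kmers, vocabs, eff_len, permissive)
    n = len(y)

    model = SequenceClassifier(
        encoder_config,
        n_scales=len(kmers),
        shared_encoder=shared_encoder,
        scalar_gate=scalar_gate,
        pooling=pooling,
        seed=adv.seed,
    )
    optimizer = Adam(model.parameters(), lr=adv.learning_rate)
    rng = np.random.default_rng(adv.seed)
    dropout_rng = (
        np.random.default_rng(adv.seed + 1) if encoder_config.dropout > 0 else None
    )
    # linear warmup into cosine decay: the standard recipe for post-norm
    # transformer stacks, which diverge or stall at a flat learning rate
    steps_per_epoch = int(np.ceil(n / adv.batch_size))
    total_steps = max(1, adv.epochs * steps_per_epoch)
    warmup_steps = max(1, total_steps // 10)
    step_idx = 0
    history = {"clean_loss": [], "adv_loss": []}
    for epoch in range(adv.epochs):
        order = rng.permutation(n)
        clean_losses, adv_losses = [], []
        for start in range(0, n, adv.batch_size):
            if step_idx < warmup_steps:
                optimizer.lr = adv.learning_rate * (step_idx + 1) / warmup_steps
            else:
                frac = (step_idx - warmup_steps) / max(1, total_steps - warmup_steps)
                optimizer.lr = adv.learning_rate * (
                    0.1 + 0.45 * (1.0 + np.cos(np.pi * frac))
                )
            step_idx += 1
            idx = order[start : start + adv.batch_size]
            batch = [(ids[idx], mask[idx]) for ids, mask in batches_all]
            try:
                c, a = adversarial_step(
                    model, batch, y[idx], optimizer, adv, dropout_rng
                )
            except RuntimeError as err:
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: {err}"
                ) from err
            clean_losses.append(c)
            adv_losses.append(a)
        history["clean_loss"].append(float(np.mean(clean_losses)))
        history["adv_loss"].append(adversarial_epoch_loss(adv_losses))
        if verbose:
            logger.info(
                "epoch %d clean %.4f adv %.4f",
                epoch, history["clean_loss"][-1], history["adv_loss"][-1],
            )
    return model, vocabs, history


def predict_proba_model(model, vocabs, sequences, kmers, max_len=None,
                        permissive: bool = False, batch_size: int = 128) -> np.ndarray:
    """Positive-class probabilities from a fitted SequenceClassifier."""
    if max_len is None:
        max_len = model.config.max_tokens
    max_len = min(max_len, model.config.max_tokens)
    batches_all = encode_batch(sequences, kmers, vocabs, max_len, permissive)
    n = batches_all[0][0].shape[0]
    out = np.empty(n)
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        batch = [(ids[sl], mask[sl]) for ids, mask in batches_all]
        out[sl] = model.predict_proba_tokens(batch)
    return out


def train(
    dataset: Dataset,
    encoder_config: EncoderConfig | None = None,
    adv: AdversarialConfig | None = None,
    folds: FoldAssignment | None = None,
    kmers=(3,),
    max_len: int = DEFAULT_MAX_LEN,
    threshold: float = 0.5,
    refit_full: bool = False,
    **fit_kwargs,
):
    """K-fold cross-validated training.

    For each fold, a fresh model is trained on the other folds and evaluated
    on the held-out fold (Sn/Sp/Acc/MCC at ``threshold`` plus AUC); the report
    carries per-fold losses, per-fold metrics and their mean. Randomness is
    fully seeded through ``adv.seed``. Returns ``(models, report)`` where
    ``models`` maps fold -> (model, vocabs); with ``refit_full`` an extra
    entry ``"full"`` is fit on all records.
    """
    from .evaluation import confusion, metrics, roc_auc  # local to avoid cycle

    adv = adv or AdversarialConfig()
    if folds is None:
        from .io import make_stratified_folds

        folds = make_stratified_folds(dataset, n_folds=5, seed=adv.seed)
    report = TrainReport()
    models = {}
    id_to_record = {r.id: r for r in dataset}
    for fold in range(folds.n_folds):
        val_ids = set(folds.fold_ids(fold))
        train_records = [r for r in dataset if r.id not in val_ids]
        val_records = [id_to_record[i] for i in folds.fold_ids(fold)]
        model, vocabs, history = fit_model(
            [r.sequence for r in train_records],
            [r.label for r in train_records],
            kmers=kmers,
            encoder_config=encoder_config,
            adv=adv,
            max_len=max_len,
            **fit_kwargs,
        )
        scores = predict_proba_model(
            model, vocabs, [r.sequence for r in val_records], kmers, max_len
        )
        y_val = np.array([r.label for r in val_records])
        m = metrics(confusion(y_val, scores, threshold=threshold))
        fold_report = {
            "Sn": m.Sn, "Sp": m.Sp, "Acc": m.Acc, "MCC": m.MCC,
            "AUC": roc_auc(y_val, scores),
        }
        report.clean_loss[fold] = history["clean_loss"]
        report.adv_loss[fold] = history["adv_loss"]
        report.fold_metrics[fold] = fold_report
        models[fold] = (model, vocabs)
    if refit_full:
        model, vocabs, _ = fit_model(
            dataset.sequences(), dataset.labels(), kmers=kmers,
            encoder_config=encoder_config, adv=adv, max_len=max_len, **fit_kwargs,
        )
        models["full"] = (model, vocabs)
    return models, report
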