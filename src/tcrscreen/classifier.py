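"""Transformer-encoder TCR-epitope binding classifier.

The model scores a CDR3β amino-acid sequence for binding to one epitope:
token embedding + sinusoidal positional encoding, a small pre-LayerNorm
transformer encoder, masked mean pooling and a linear head producing a single
pre-sigmoid score (log-odds of binding). Positives come from deconvolved
phage-screen binders; negatives from input-library sequences absent from the
screen output. Because the whole CDR3β (flanks included) is the input unit,
a trained model scores repertoire sequences whose core lengths were never
seen in training.

Training, cross-validation and scoring are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .alphabet import AMINO_ACIDS
from .autodiff import Adam, Tensor, layer_norm


@dataclass(frozen=True)
class TokenVocabulary:
    """Amino-acid token vocabulary with padding and begin/end markers."""

    max_len: int = 30  # longest raw sequence; +2 slots for BOS/EOS

    PAD: int = 0
    BOS: int = 21
    EOS: int = 22

    @property
    def size(self) -> int:
        return 23

    @property
    def padded_len(self) -> int:
        return self.max_len + 2

    def token(self, aa: str) -> int:
        idx = AMINO_ACIDS.find(aa)
        if idx < 0:
            raise ValueError(f"non-standard amino acid {aa!r}")
        return idx + 1

    def letter(self, tok: int) -> str:
        return AMINO_ACIDS[tok - 1]


def encode_sequences(
    seqs: list[str], vocab: TokenVocabulary, pad_to: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences as right-padded token rows plus a real-token mask.

    Rows are ``BOS + residues + EOS`` padded to ``pad_to + 2`` columns
    (default: the longest sequence in the batch); ``mask`` is True on real
    tokens, False on padding. Padding width never changes model scores:
    padded positions receive exactly zero attention weight and are excluded
    from pooling. Raises on non-standard residues (naming the sequence) and
    on sequences longer than the vocabulary maximum.
    """
    n = len(seqs)
    width = max((len(s) for s in seqs), default=0) if pad_to is None else pad_to
    if width > vocab.max_len:
        raise ValueError(f"pad width {width} exceeds the maximum {vocab.max_len}")
    L = width + 2
    tokens = np.full((n, L), vocab.PAD, dtype=np.int64)
    mask = np.zeros((n, L), dtype=bool)
    for i, seq in enumerate(seqs):
        if len(seq) > vocab.max_len:
            raise ValueError(
                f"sequence {seq!r} exceeds the maximum length {vocab.max_len}"
            )
        try:
            row = [vocab.BOS] + [vocab.token(c) for c in seq] + [vocab.EOS]
        except ValueError:
            raise ValueError(f"non-standard amino acid in sequence {seq!r}") from None
        tokens[i, : len(row)] = row
        mask[i, : len(row)] = True
    return tokens, mask


def decode_sequences(tokens: np.ndarray, vocab: TokenVocabulary) -> list[str]:
    """Invert :func:`encode_sequences` on the real (non-special) positions."""
    out = []
    for row in tokens:
        letters = [
            vocab.letter(int(t))
            for t in row
            if int(t) not in (vocab.PAD, vocab.BOS, vocab.EOS)
        ]
        out.append("".join(letters))
    return out


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the encoder and its training loop."""

    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    neg_ratio: float = 1.0  # negatives sampled per positive
    val_fraction: float = 0.1
    max_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("n_heads must divide d_model")
        for name in ("d_model", "n_heads", "n_layers", "d_ff", "batch_size",
                     "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _positional_encoding(length: int, d_model: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((length, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def _init_params(cfg: ClassifierConfig, vocab: TokenVocabulary,
                 rng: np.random.Generator) -> dict[str, Tensor]:
    d, ff = cfg.d_model, cfg.d_ff

    def glorot(*shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    params: dict[str, Tensor] = {
        "embed": Tensor(rng.normal(0.0, 0.02, size=(vocab.size, d)),
                        requires_grad=True),
    }
    for layer in range(cfg.n_layers):
        p = f"l{layer}."
        for name in ("wq", "wk", "wv", "wo"):
            params[p + name] = glorot(d, d)
        for name in ("bq", "bk", "bv", "bo"):
            params[p + name] = Tensor(np.zeros(d), requires_grad=True)
        params[p + "ln1_g"] = Tensor(np.ones(d), requires_grad=True)
        params[p + "ln1_b"] = Tensor(np.zeros(d), requires_grad=True)
        params[p + "ln2_g"] = Tensor(np.ones(d), requires_grad=True)
        params[p + "ln2_b"] = Tensor(np.zeros(d), requires_grad=True)
        params[p + "w1"] = glorot(d, ff)
        params[p + "b1"] = Tensor(np.zeros(ff), requires_grad=True)
        params[p + "w2"] = glorot(ff, d)
        params[p + "b2"] = Tensor(np.zeros(d), requires_grad=True)
    params["lnf_g"] = Tensor(np.ones(d), requires_grad=True)
    params["lnf_b"] = Tensor(np.zeros(d), requires_grad=True)
    params["head_w"] = glorot(d, 1)
    params["head_b"] = Tensor(np.zeros(1), requires_grad=True)
    return params


def _forward(
    params: dict[str, Tensor],
    cfg: ClassifierConfig,
    vocab: TokenVocabulary,
    tokens: np.ndarray,
    mask: np.ndarray,
    *,
    dropout_rng: np.random.Generator | None = None,
) -> Tensor:
    """Compute per-sequence logits; dropout active iff ``dropout_rng`` given."""
    B, L = tokens.shape
    d, H = cfg.d_model, cfg.n_heads
    dh = d // H

    def drop(t: Tensor) -> Tensor:
        if dropout_rng is None or cfg.dropout <= 0:
            return t
        keep = (dropout_rng.random(t.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
        return t * Tensor(keep)

    x = params["embed"].take_rows(tokens) * np.sqrt(d)
    x = x + Tensor(_positional_encoding(L, d))
    x = drop(x)

    attn_bias = np.where(mask[:, None, None, :], 0.0, -1e9)  # (B,1,1,L)
    scale = 1.0 / np.sqrt(dh)
    for layer in range(cfg.n_layers):
        p = f"l{layer}."
        h = layer_norm(x, params[p + "ln1_g"], params[p + "ln1_b"])

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dh).transpose((0, 2, 1, 3))

        q = heads(h @ params[p + "wq"] + params[p + "bq"])
        k = heads(h @ params[p + "wk"] + params[p + "bk"])
        v = heads(h @ params[p + "wv"] + params[p + "bv"])
        scores = (q @ k.transpose((0, 1, 3, 2))) * scale + Tensor(attn_bias)
        attn = drop(scores.softmax(axis=-1))
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, L, d)
        x = x + drop(ctx @ params[p + "wo"] + params[p + "bo"])

        h2 = layer_norm(x, params[p + "ln2_g"], params[p + "ln2_b"])
        ffn = (h2 @ params[p + "w1"] + params[p + "b1"]).relu()
        x = x + drop(ffn @ params[p + "w2"] + params[p + "b2"])

    h = layer_norm(x, params["lnf_g"], params["lnf_b"])
    maskf = mask.astype(float)[:, :, None]
    pooled = (h * Tensor(maskf)).sum(axis=1) * Tensor(
        1.0 / maskf.sum(axis=1)
    )  # masked mean over real tokens
    logits = pooled @ params["head_w"] + params["head_b"]
    return logits.reshape(B)


@dataclass
class TrainedModel:
    """Trained classifier: weights + vocabulary + config + training metadata."""

    params: dict[str, Tensor]
    config: ClassifierConfig
    vocab: TokenVocabulary
    history: dict = field(default_factory=dict)

    def score(self, seqs: list[str], batch_size: int = 512) -> np.ndarray:
        """One finite log-odds score per sequence; batching-invariant."""
        if not seqs:
            return np.zeros(0)
        out = np.empty(len(seqs))
        for start in range(0, len(seqs), batch_size):
            chunk = seqs[start : start + batch_size]
            tokens, mask = encode_sequences(chunk, self.vocab)
            out[start : start + len(chunk)] = _forward(
                self.params, self.config, self.vocab, tokens, mask
            ).data
        return out

    def weights_digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.params.items()}
        meta = json.dumps(
            {"config": asdict(self.config), "max_len": self.vocab.max_len}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ClassifierConfig(**meta["config"])
        vocab = TokenVocabulary(max_len=meta["max_len"])
        params = {
            name: Tensor(data[name], requires_grad=True)
            for name in data.files
            if name != "__meta__"
        }
        return cls(params=params, config=cfg, vocab=vocab)


def _bce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    # softplus(z) - y*z == -[y*log(sig(z)) + (1-y)*log(1-sig(z))], stable
    return (logits.softplus() - logits * Tensor(labels)).mean()


def train_classifier(
    positives: list[str], negatives: list[str], config: ClassifierConfig
) -> TrainedModel:
    """Train the binder/non-binder classifier with early stopping.

    ``positives`` and ``negatives`` must be disjoint (negatives are, by
    construction, input-library sequences never seen in the screen output).
    Negatives are subsampled to ``config.neg_ratio`` per positive when more
    are supplied. A stratified validation split monitors the binary
    cross-entropy; the best-validation weights are restored on stop.
    """
    if not positives or not negatives:
        raise ValueError("both positive and negative sets must be non-empty")
    overlap = set(positives) & set(negatives)
    if overlap:
        raise ValueError(
            f"{len(overlap)} sequence(s) appear in both classes, e.g. "
            f"{sorted(overlap)[:3]}; negatives must be disjoint from positives"
        )
    rng = np.random.default_rng(config.seed)
    n_neg_target = int(round(config.neg_ratio * len(positives)))
    if 0 < n_neg_target < len(negatives):
        idx = rng.choice(len(negatives), size=n_neg_target, replace=False)
        negatives = [negatives[i] for i in sorted(idx)]

    vocab = TokenVocabulary(max_len=config.max_len)
    seqs = list(positives) + list(negatives)
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    tokens, mask = encode_sequences(seqs, vocab)

    # stratified train/validation split
    order = rng.permutation(len(seqs))
    tokens, mask, labels = tokens[order], mask[order], labels[order]
    n_val = max(2, int(round(config.val_fraction * len(seqs))))
    val_idx = np.concatenate(
        [np.where(labels == 1)[0][: max(1, n_val // 2)],
         np.where(labels == 0)[0][: max(1, n_val // 2)]]
    )
    train_idx = np.setdiff1d(np.arange(len(seqs)), val_idx)

    params = _init_params(config, vocab, rng)
    opt = Adam(list(params.values()), lr=config.lr)
    drop_rng = np.random.default_rng(config.seed + 1)

    best_val = np.inf
    best_weights = {k: p.data.copy() for k, p in params.items()}
    stale = 0
    history = {"train_loss": [], "val_loss": []}
    for _epoch in range(config.max_epochs):
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            opt.zero_grad()
            logits = _forward(params, config, vocab, tokens[batch], mask[batch],
                              dropout_rng=drop_rng)
            loss = _bce_loss(logits, labels[batch])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        history["train_loss"].append(epoch_loss / len(perm))

        val_logits = _forward(params, config, vocab, tokens[val_idx], mask[val_idx])
        val_loss = float(_bce_loss(val_logits, labels[val_idx]).data)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = {k: p.data.copy() for k, p in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    for k, p in params.items():
        p.data = best_weights[k]
    return TrainedModel(params=params, config=config, vocab=vocab, history=history)


def score_sequences(model: TrainedModel, seqs: list[str]) -> np.ndarray:
    """Score sequences with a trained model (log-odds scale)."""
    return model.score(seqs)


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation with ties at 0.5.

    Equals the trapezoidal area under the ROC curve; requires at least one
    positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks -> ties count 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CVReport:
    """Per-fold ROC curves and AUCs from stratified cross-validation."""

    fold_aucs: list[float]
    roc_curves: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per fold

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_json(self, path) -> None:
        payload = {
            "mean_auc": self.mean_auc,
            "fold_aucs": self.fold_aucs,
            "roc_curves": [
                {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
                for fpr, tpr in self.roc_curves
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def crossvalidate(
    positives: list[str],
    negatives: list[str],
    config: ClassifierConfig,
    n_folds: int = 5,
) -> CVReport:
    """Stratified k-fold cross-validation of the classifier.

    Each fold trains on the remaining folds and scores its held-out
    sequences; folds partition the data with no leakage. Reports per-fold
    ROC curves and AUCs plus their mean.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if min(len(positives), len(negatives)) < n_folds:
        raise ValueError("each class must have at least n_folds sequences")
    seqs = np.array(list(positives) + list(negatives))
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    aucs: list[float] = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for fold, (train, test) in enumerate(skf.split(seqs, labels)):
        fold_cfg = ClassifierConfig(**{**asdict(config), "seed": config.seed + fold})
        model = train_classifier(
            list(seqs[train][labels[train] == 1]),
            list(seqs[train][labels[train] == 0]),
            fold_cfg,
        )
        scores = model.score(list(seqs[test]))
        aucs.append(compute_auc(scores, labels[test]))
        fpr, tpr, _ = roc_curve(labels[test], scores)
        curves.append((fpr, tpr))
    return CVReport(fold_aucs=aucs, roc_curves=curves)
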