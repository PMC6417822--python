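"""Relation classifier: does an abstract support the queried association?

The primary extractor is a 2-layer bidirectional LSTM over encoded concept
sequences. Each position feeds the concatenation of a learned concept
embedding, the 136-slot semantic-category one-hot, and the two ontology
flag bits; the classification representation is the concatenation of the
final forward and final backward top-layer hidden states (2·hidden_dim).
Training uses Adam on softmax cross-entropy, jointly with the embedding
matrix.

A maximum-entropy (logistic regression on bag-of-concept counts) baseline
extractor is provided behind the same interface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import EncodedArticle
from .types import N_SEMANTIC_SLOTS

__all__ = [
    "ClassifierConfig",
    "ClassifierOutput",
    "BiLSTMClassifier",
    "MaxentClassifier",
    "forward",
    "train_classifier",
    "precision_recall_f1",
]


@dataclass
class ClassifierConfig:
    """Architecture and optimisation settings.

    Defaults are the full-scale values (512-dim embeddings, 2×1000 hidden,
    Adam step 4e-5, batch 64, 300-position inputs over a 30,000+4 concept
    vocabulary). Tests and the synthetic pipeline shrink ``embed_dim`` /
    ``hidden_dim`` — the architecture is unchanged, only widths.
    """

    embed_dim: int = 512
    hidden_dim: int = 1000
    num_layers: int = 2
    max_len: int = 300
    vocab_size: int = 30_004
    learning_rate: float = 0.00004
    batch_size: int = 64
    epochs: int = 5
    pooling: str = "final"  # "final" or "mean"
    use_confidence: bool = False  # extra per-position input channel

    @property
    def input_width(self) -> int:
        return self.embed_dim + N_SEMANTIC_SLOTS + 2 + (1 if self.use_confidence else 0)


@dataclass
class ClassifierOutput:
    """Per-article verdict: association probability + pooled representation."""

    p_association: float
    embedding: np.ndarray


class BiLSTMClassifier:
    """Two-layer bidirectional LSTM classifier with learned embeddings."""

    def __init__(self, config: ClassifierConfig, seed: int = 0):
        if config.num_layers != 2:
            raise ValueError("this implementation is fixed at 2 recurrent layers")
        self.config = config
        rng = np.random.default_rng(seed)
        E, H, D0 = config.embed_dim, config.hidden_dim, config.input_width
        self.params: dict[str, np.ndarray] = {
            # small scale keeps never-trained (rare/unseen) concepts near the
            # zero vector, so prediction falls back on the category channel
            "emb": rng.normal(0.0, 0.01, (config.vocab_size, E)),
            "out_W": rng.normal(0.0, 1.0 / np.sqrt(2 * H), (2 * H, 2)),
            "out_b": np.zeros(2),
        }
        for layer, in_dim in (("l0", D0), ("l1", 2 * H)):
            for direction in ("f", "b"):
                for k, v in nn.init_lstm_params(in_dim, H, rng).items():
                    self.params[f"{layer}{direction}_{k}"] = v

    # -- batching helpers -------------------------------------------------

    def _stack(self, batch: list[EncodedArticle]):
        cfg = self.config
        for enc in batch:
            if len(enc.token_ids) != cfg.max_len:
                raise ValueError(
                    f"encoded length {len(enc.token_ids)} != configured max_len {cfg.max_len}"
                )
        tokens = np.stack([e.token_ids for e in batch])
        cats = np.stack([e.category_idx for e in batch])
        gene = np.stack([e.gene_flags for e in batch]).astype(np.float64)
        dis = np.stack([e.disease_flags for e in batch]).astype(np.float64)
        conf = np.stack([e.confidences for e in batch])
        lengths = np.array([e.true_length for e in batch])
        T_eff = max(int(lengths.max()), 1)
        return (
            tokens[:, :T_eff],
            cats[:, :T_eff],
            gene[:, :T_eff],
            dis[:, :T_eff],
            conf[:, :T_eff],
            lengths,
        )

    def _subparams(self, prefix: str) -> dict[str, np.ndarray]:
        return {k: self.params[f"{prefix}_{k}"] for k in ("Wx", "Wh", "b")}

    def _forward_internal(self, batch: list[EncodedArticle]):
        cfg = self.config
        tokens, cats, gene, dis, conf, lengths = self._stack(batch)
        B, T = tokens.shape
        H = cfg.hidden_dim

        onehot = np.zeros((B, T, N_SEMANTIC_SLOTS))
        valid = cats >= 0
        b_idx, t_idx = np.nonzero(valid)
        onehot[b_idx, t_idx, cats[valid]] = 1.0

        channels = [self.params["emb"][tokens], onehot, gene[..., None], dis[..., None]]
        if cfg.use_confidence:
            channels.append(conf[..., None])
        X0 = np.concatenate(channels, axis=2)
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(np.float64)

        fw0, cache_f0 = nn.lstm_forward(X0, mask, self._subparams("l0f"))
        X0r = nn.reverse_valid(X0, lengths)
        bw0r, cache_b0 = nn.lstm_forward(X0r, mask, self._subparams("l0b"))
        bw0 = nn.reverse_valid(bw0r, lengths)

        X1 = np.concatenate([fw0, bw0], axis=2)
        fw1, cache_f1 = nn.lstm_forward(X1, mask, self._subparams("l1f"))
        X1r = nn.reverse_valid(X1, lengths)
        bw1r, cache_b1 = nn.lstm_forward(X1r, mask, self._subparams("l1b"))

        if cfg.pooling == "mean":
            denom = mask.sum(axis=1, keepdims=True)
            bw1 = nn.reverse_valid(bw1r, lengths)
            rep = np.concatenate(
                [
                    (fw1 * mask[..., None]).sum(axis=1) / denom,
                    (bw1 * mask[..., None]).sum(axis=1) / denom,
                ],
                axis=1,
            )
        elif cfg.pooling == "final":
            # masked recurrence: state at T-1 == state at each true final position
            rep = np.concatenate([fw1[:, T - 1], bw1r[:, T - 1]], axis=1)
        else:
            raise ValueError(f"unknown pooling {cfg.pooling!r}")

        logits = rep @ self.params["out_W"] + self.params["out_b"]
        cache = {
            "tokens": tokens,
            "lengths": lengths,
            "mask": mask,
            "rep": rep,
            "H": H,
            "T": T,
            "caches": (cache_f0, cache_b0, cache_f1, cache_b1),
        }
        return logits, rep, cache

    def forward_batch(self, batch: list[EncodedArticle]) -> tuple[np.ndarray, np.ndarray]:
        """Class probabilities (B, 2) and pooled representations (B, 2H)."""
        logits, rep, _ = self._forward_internal(batch)
        return nn.softmax(logits), rep

    def forward(self, encoded: EncodedArticle) -> ClassifierOutput:
        probs, rep = self.forward_batch([encoded])
        return ClassifierOutput(p_association=float(probs[0, 1]), embedding=rep[0])

    @property
    def embedding_dim(self) -> int:
        return 2 * self.config.hidden_dim

    # -- training ---------------------------------------------------------

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        H, T = cache["H"], cache["T"]
        lengths, tokens = cache["lengths"], cache["tokens"]
        mask = cache["mask"]
        cache_f0, cache_b0, cache_f1, cache_b1 = cache["caches"]

        grads = {
            "out_W": cache["rep"].T @ dlogits,
            "out_b": dlogits.sum(axis=0),
        }
        drep = dlogits @ self.params["out_W"].T

        B = dlogits.shape[0]
        if cfg.pooling == "mean":
            weight = mask / mask.sum(axis=1, keepdims=True)  # (B, T)
            dH_f1 = weight[..., None] * drep[:, None, :H]
            dH_b1 = weight[..., None] * drep[:, None, H:]
            dH_b1r = nn.reverse_valid(dH_b1, lengths)
        else:
            dH_f1 = np.zeros((B, T, H))
            dH_f1[:, T - 1] = drep[:, :H]
            dH_b1r = np.zeros((B, T, H))
            dH_b1r[:, T - 1] = drep[:, H:]

        dX1_a, g_f1 = nn.lstm_backward(dH_f1, cache_f1)
        dX1r_b, g_b1 = nn.lstm_backward(dH_b1r, cache_b1)
        dX1 = dX1_a + nn.reverse_valid(dX1r_b, lengths)

        dH_f0 = dX1[..., :H]
        dH_b0r = nn.reverse_valid(np.ascontiguousarray(dX1[..., H:]), lengths)
        dX0_a, g_f0 = nn.lstm_backward(dH_f0, cache_f0)
        dX0r_b, g_b0 = nn.lstm_backward(dH_b0r, cache_b0)
        dX0 = dX0_a + nn.reverse_valid(dX0r_b, lengths)

        demb_tokens = dX0[..., : cfg.embed_dim]
        demb = np.zeros_like(self.params["emb"])
        np.add.at(demb, tokens, demb_tokens)
        grads["emb"] = demb
        for prefix, g in (("l0f", g_f0), ("l0b", g_b0), ("l1f", g_f1), ("l1b", g_b1)):
            for k, v in g.items():
                grads[f"{prefix}_{k}"] = v
        return grads

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "BiLSTMClassifier":
        data = np.load(path, allow_pickle=False)
        config = ClassifierConfig(**json.loads(str(data["__config__"])))
        model = cls(config, seed=0)
        model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model


def forward(encoded: EncodedArticle, model) -> ClassifierOutput:
    """Functional facade over ``model.forward``."""
    return model.forward(encoded)


def train_classifier(
    train: list[tuple[EncodedArticle, bool]],
    config: ClassifierConfig,
    seed: int = 0,
    model: BiLSTMClassifier | None = None,
) -> tuple[BiLSTMClassifier, list[float]]:
    """Train the recurrent classifier; returns (model, per-epoch mean loss).

    Deterministic given ``seed``: initialisation, shuffling and batching all
    derive from it. ``config.epochs == 0`` returns the untrained model with
    an empty loss trace. Raises on a single-class training set.
    """
    labels = {bool(y) for _, y in train}
    if config.epochs > 0 and len(labels) < 2:
        raise ValueError("training set must contain both classes")
    model = model or BiLSTMClassifier(config, seed=seed)
    opt = nn.Adam(config.learning_rate)
    rng = np.random.default_rng(seed + 1)
    losses: list[float] = []
    n = len(train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [train[i][0] for i in idx]
            y = np.array([int(train[i][1]) for i in idx])
            logits, _, cache = model._forward_internal(batch)
            loss, dlogits = nn.softmax_xent(logits, y)
            grads = model._backward(dlogits, cache)
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    return model, losses


class MaxentClassifier:
    """Maximum-entropy baseline: logistic regression on concept counts.

    Features are bag-of-concept counts over the vocabulary (specials
    excluded). Exposes the same ``forward`` surface as the recurrent
    classifier; its "embedding" is the single decision-function value.
    """

    def __init__(self, config: ClassifierConfig, seed: int = 0):
        from sklearn.linear_model import LogisticRegression

        self.config = config
        self._clf = LogisticRegression(max_iter=1000, random_state=seed)
        self._fitted = False

    def _features(self, batch: list[EncodedArticle]) -> np.ndarray:
        X = np.zeros((len(batch), self.config.vocab_size))
        for i, enc in enumerate(batch):
            ids = enc.token_ids[: enc.true_length]
            np.add.at(X[i], ids[ids >= 4], 1.0)
        return X

    def fit(self, train: list[tuple[EncodedArticle, bool]]) -> "MaxentClassifier":
        X = self._features([e for e, _ in train])
        y = np.array([int(lbl) for _, lbl in train])
        self._clf.fit(X, y)
        self._fitted = True
        return self

    def forward_batch(self, batch: list[EncodedArticle]) -> tuple[np.ndarray, np.ndarray]:
        X = self._features(batch)
        probs = self._clf.predict_proba(X)
        margin = self._clf.decision_function(X).reshape(-1, 1)
        return probs, margin

    def forward(self, encoded: EncodedArticle) -> ClassifierOutput:
        probs, margin = self.forward_batch([encoded])
        return ClassifierOutput(p_association=float(probs[0, 1]), embedding=margin[0])

    @property
    def embedding_dim(self) -> int:
        return 1


def precision_recall_f1(
    predictions: list[bool] | np.ndarray, golds: list[bool] | np.ndarray
) -> tuple[float, float, float]:
    """Standard precision/recall/F1 for boolean predictions.

    With no predicted positives, precision is undefined and reported as 0
    with a warning (recall and F1 are then 0 as well when positives exist).
    """
    preds = np.asarray(predictions, dtype=bool)
    gold = np.asarray(golds, dtype=bool)
    if preds.shape != gold.shape:
        raise ValueError("predictions and golds must have equal length")
    tp = int(np.sum(preds & gold))
    fp = int(np.sum(preds & ~gold))
    fn = int(np.sum(~preds & gold))
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision undefined, reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f1
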