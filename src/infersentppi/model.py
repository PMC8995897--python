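"""InferSent_PN: CNN sentence encoder + pair classifier for PPI prediction.

Each protein sentence (a stack of GO-term vectors) is encoded by a small
convolutional network: stacked 1-D convolutions along the token axis with
ReLU, where after every layer the channel-wise max over time is taken and
the per-layer pooled vectors are concatenated into a fixed-length sentence
embedding, independent of sentence length (hierarchical-ConvNet pooling).
GO-term "words" carry no meaningful order, so sentences are built in a
canonical sorted order; the default kernel size of 2 slides over adjacent
sorted tokens, which makes a term repeated by its reliability weight form
a distinctive repeated-token window — the route by which annotation
weights reach the encoder (a max-pool alone is blind to repetition).
With kernel 1 the encoder is exactly permutation-invariant.

The two sentence embeddings u, v are combined into the InferSent feature
vector [u; v; |u - v|; u ⊙ v], passed through one hidden layer with ReLU
and dropout, and classified by a 2-way softmax. The decision rule is
strict: a pair is called positive iff P(positive) > P(negative), so an
exact tie is negative.

Training minimises 2-class cross-entropy with Adam. Everything is plain
numpy with hand-written backpropagation, single-threaded and seeded, so a
fixed seed and corpus reproduce the trained parameters exactly. Examples
are processed one at a time and gradients averaged over the mini-batch,
which is equivalent to zero-padding variable-length sentences and masking
the max-pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .corpus import PairExample, ProteinSentence, build_sentence
from .evaluation import MetricsReport, full_report

Example = tuple[ProteinSentence, ProteinSentence, int]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters for InferSent_PN."""

    embed_dim: int = 64
    conv_channels: tuple[int, ...] = (32, 32)
    kernel_size: int = 2
    pool: str = "max"
    hidden_dim: int = 64
    dropout: float = 0.1
    token_dropout: float = 0.0  # fraction of sentence tokens dropped per training pass
    lr: float = 1e-3
    batch_size: int = 2
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.conv_channels:
            raise ValueError("need at least one conv layer")
        if self.pool != "max":
            raise ValueError("only max pooling is supported")
        self.conv_channels = tuple(self.conv_channels)

    @property
    def sentence_dim(self) -> int:
        return int(sum(self.conv_channels))


@dataclass
class PredictionResult:
    """Softmax class probabilities and the hard label (1 pos / 0 neg)."""

    p_positive: float
    p_negative: float
    label: int


class PairModel:
    """Trained InferSent_PN parameters bound to a configuration."""

    classes = ("positive", "negative")

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    # -- persistence ---------------------------------------------------

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.json`` (config) and ``<prefix>.npz`` (weights)."""
        cfg = asdict(self.config)
        cfg["conv_channels"] = list(cfg["conv_channels"])
        with open(prefix + ".json", "w") as fh:
            json.dump(cfg, fh, indent=1)
        np.savez(prefix + ".npz", **self.params)

    @classmethod
    def load(cls, prefix: str) -> "PairModel":
        with open(prefix + ".json") as fh:
            cfg = json.load(fh)
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        data = np.load(prefix + ".npz")
        return cls(ModelConfig(**cfg), {k: data[k] for k in data.files})


# -- parameter initialisation -----------------------------------------


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    d_in = config.embed_dim
    k = config.kernel_size
    for li, c in enumerate(config.conv_channels):
        scale = np.sqrt(2.0 / (k * d_in))
        params[f"convW{li}"] = rng.normal(0.0, scale, size=(k, d_in, c))
        params[f"convb{li}"] = np.zeros(c)
        d_in = c
    zdim = 4 * config.sentence_dim
    params["W1"] = rng.normal(0.0, np.sqrt(2.0 / zdim), size=(zdim, config.hidden_dim))
    params["b1"] = np.zeros(config.hidden_dim)
    params["W2"] = rng.normal(0.0, np.sqrt(2.0 / config.hidden_dim), size=(config.hidden_dim, 2))
    params["b2"] = np.zeros(2)
    return params


# -- encoder forward/backward -----------------------------------------


def _conv1d(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution along the token axis.

    X: (T, d_in); W: (k, d_in, c). Sequences shorter than the kernel are
    zero-padded up to k so every sentence yields at least one position.
    """
    k = W.shape[0]
    if X.shape[0] < k:
        X = np.vstack([X, np.zeros((k - X.shape[0], X.shape[1]))])
    T_out = X.shape[0] - k + 1
    out = np.tile(b, (T_out, 1))
    for o in range(k):
        out += X[o : o + T_out] @ W[o]
    return out


def _encode_forward(params: dict, config: ModelConfig, X: np.ndarray):
    """Run the encoder, returning the embedding and a backprop cache."""
    cache = []
    H = X
    pooled = []
    for li in range(len(config.conv_channels)):
        Xl = H
        A = _conv1d(Xl, params[f"convW{li}"], params[f"convb{li}"])
        H = np.maximum(A, 0.0)
        arg = H.argmax(axis=0)
        pooled.append(H[arg, np.arange(H.shape[1])])
        cache.append((Xl, A, H, arg))
    return np.concatenate(pooled), cache


def _encode_backward(params: dict, config: ModelConfig, cache, dU: np.ndarray, grads: dict):
    """Backprop dU (gradient wrt the concatenated embedding) through the encoder."""
    channels = config.conv_channels
    k = config.kernel_size
    # split dU into per-layer pooled gradients
    splits = np.cumsum(channels)[:-1]
    dpooled = np.split(dU, splits)
    dH_next: np.ndarray | None = None  # gradient flowing from layer above
    for li in reversed(range(len(channels))):
        Xl, A, H, arg = cache[li]
        dH = np.zeros_like(H)
        dH[arg, np.arange(H.shape[1])] += dpooled[li]
        if dH_next is not None:
            dH += dH_next
        dA = dH * (A > 0.0)
        W = params[f"convW{li}"]
        Xp = Xl
        if Xp.shape[0] < k:
            Xp = np.vstack([Xp, np.zeros((k - Xp.shape[0], Xp.shape[1]))])
        T_out = dA.shape[0]
        dXp = np.zeros_like(Xp)
        for o in range(k):
            grads[f"convW{li}"][o] += Xp[o : o + T_out].T @ dA
            dXp[o : o + T_out] += dA @ W[o].T
        grads[f"convb{li}"] += dA.sum(axis=0)
        dH_next = dXp[: Xl.shape[0]]


# -- feature composition ----------------------------------------------


def combine_features(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """InferSent pair features: concatenation [u, v, |u-v|, u*v]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"embedding shapes differ: {u.shape} vs {v.shape}")
    return np.concatenate([u, v, np.abs(u - v), u * v])


def _classifier_forward(params: dict, z: np.ndarray, drop_mask: np.ndarray | None):
    h_pre = z @ params["W1"] + params["b1"]
    h = np.maximum(h_pre, 0.0)
    h_d = h * drop_mask if drop_mask is not None else h
    logits = h_d @ params["W2"] + params["b2"]
    logits = logits - logits.max()
    exp = np.exp(logits)
    probs = exp / exp.sum()
    return probs, (z, h_pre, h_d)


def _pair_forward(params, config, si, sj, drop_mask=None):
    u, cu = _encode_forward(params, config, si.matrix)
    v, cv = _encode_forward(params, config, sj.matrix)
    z = combine_features(u, v)
    probs, ccls = _classifier_forward(params, z, drop_mask)
    return probs, (u, v, cu, cv, ccls, drop_mask)


def _pair_backward(params, config, fwd_cache, dlogits, grads):
    u, v, cu, cv, (z, h_pre, h_d), drop_mask = fwd_cache
    grads["W2"] += np.outer(h_d, dlogits)
    grads["b2"] += dlogits
    dh = dlogits @ params["W2"].T
    if drop_mask is not None:
        dh = dh * drop_mask
    dh = dh * (h_pre > 0.0)
    grads["W1"] += np.outer(z, dh)
    grads["b1"] += dh
    dz = dh @ params["W1"].T
    E = len(u)
    dzu, dzv, dza, dzm = dz[:E], dz[E : 2 * E], dz[2 * E : 3 * E], dz[3 * E :]
    s = np.sign(u - v)
    du = dzu + s * dza + v * dzm
    dv = dzv - s * dza + u * dzm
    _encode_backward(params, config, cu, du, grads)
    _encode_backward(params, config, cv, dv, grads)


def _drop_tokens(s: ProteinSentence, p: float, rng: np.random.Generator) -> ProteinSentence:
    """Word-dropout regularisation: drop each token with probability p.

    At least one token is always kept. Applied only during training; it
    discourages the encoder from memorising whole sentences (protein
    identities) instead of term overlap.
    """
    keep = rng.random(len(s.term_ids)) >= p
    if not keep.any():
        keep[int(rng.integers(len(keep)))] = True
    return ProteinSentence(
        protein_id=s.protein_id,
        term_ids=[t for t, k in zip(s.term_ids, keep) if k],
        matrix=s.matrix[keep],
    )


# -- public operations -------------------------------------------------


def encode_sentence(model: PairModel, s: ProteinSentence) -> np.ndarray:
    """Fixed-length sentence embedding of a protein sentence."""
    if s.matrix.shape[1] != model.config.embed_dim:
        raise ValueError(
            f"sentence vectors have dim {s.matrix.shape[1]}, "
            f"model expects {model.config.embed_dim}"
        )
    emb, _ = _encode_forward(model.params, model.config, s.matrix)
    return emb


def predict(
    model: PairModel,
    si: ProteinSentence,
    sj: ProteinSentence,
    symmetric: bool = False,
) -> PredictionResult:
    """Classify a protein pair; positive iff P(positive) strictly exceeds P(negative).

    With ``symmetric=True`` the probabilities are averaged over both
    argument orders (off by default).
    """
    probs, _ = _pair_forward(model.params, model.config, si, sj)
    if symmetric:
        probs2, _ = _pair_forward(model.params, model.config, sj, si)
        probs = 0.5 * (probs + probs2)
    p_pos, p_neg = float(probs[0]), float(probs[1])
    return PredictionResult(p_positive=p_pos, p_negative=p_neg, label=int(p_pos > p_neg))


def train(
    corpus_train: Sequence[Example], config: ModelConfig
) -> tuple[PairModel, list[float]]:
    """Train InferSent_PN; returns the model and the per-epoch loss log."""
    labels = {lab for _, _, lab in corpus_train}
    if len(corpus_train) < 2 or len(labels) < 2:
        raise ValueError("training corpus must contain both classes and >= 2 examples")
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    n = len(corpus_train)
    loss_log: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = {k: np.zeros_like(p) for k, p in params.items()}
            for idx in batch:
                si, sj, lab = corpus_train[idx]
                if config.token_dropout > 0.0:
                    si = _drop_tokens(si, config.token_dropout, rng)
                    sj = _drop_tokens(sj, config.token_dropout, rng)
                mask = None
                if config.dropout > 0.0:
                    keep = rng.random(config.hidden_dim) >= config.dropout
                    mask = keep / (1.0 - config.dropout)
                probs, cache = _pair_forward(params, config, si, sj, mask)
                target = 0 if lab == 1 else 1  # output unit 0 = positive
                epoch_loss += -np.log(max(probs[target], 1e-12))
                dlogits = probs.copy()
                dlogits[target] -= 1.0
                _pair_backward(params, config, cache, dlogits / len(batch), grads)
            t_step += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**t_step)
                vhat = v2[k] / (1 - beta2**t_step)
                params[k] -= config.lr * mhat / (np.sqrt(vhat) + eps)
        loss_log.append(epoch_loss / n)
    return PairModel(config, params), loss_log


# -- statsmodels-style model / results objects ------------------------


class InferSentPN:
    """The pair-classification model, built from a labeled example corpus.

    Parameters
    ----------
    examples : list of (ProteinSentence, ProteinSentence, label)
    config : ModelConfig, architecture and training settings; ``embed_dim``
        is inferred from the sentences when left at a mismatching default.
    """

    def __init__(self, examples: Sequence[Example], config: ModelConfig | None = None):
        if not examples:
            raise ValueError("empty example corpus")
        dim = examples[0][0].matrix.shape[1]
        if config is None:
            config = ModelConfig(embed_dim=dim)
        elif config.embed_dim != dim:
            raise ValueError(
                f"config.embed_dim={config.embed_dim} but sentences have dim {dim}"
            )
        self.examples = list(examples)
        self.config = config

    @classmethod
    def from_corpus(
        cls,
        pairs: Sequence[PairExample],
        pgaa,
        vectors,
        weighted: bool = True,
        weight_cap: int = 10,
        config: ModelConfig | None = None,
    ) -> "InferSentPN":
        """Build the example corpus from pair records and annotations."""
        cache: dict[str, ProteinSentence] = {}

        def sent(p: str) -> ProteinSentence:
            if p not in cache:
                cache[p] = build_sentence(p, pgaa, vectors, weighted, weight_cap)
            return cache[p]

        examples = [(sent(p.protein_i), sent(p.protein_j), p.label) for p in pairs]
        if config is None:
            config = ModelConfig(embed_dim=vectors.dim)
        return cls(examples, config)

    def fit(self) -> "InferSentPNResults":
        model, loss_log = train(self.examples, self.config)
        return InferSentPNResults(self, model, loss_log)


class InferSentPNResults:
    """Fit results: trained parameters, loss log, prediction and scoring."""

    def __init__(self, model_spec: InferSentPN, pair_model: PairModel, loss_log: list[float]):
        self.model_spec = model_spec
        self.pair_model = pair_model
        self.loss_log = loss_log

    def predict(self, si: ProteinSentence, sj: ProteinSentence, symmetric: bool = False) -> PredictionResult:
        return predict(self.pair_model, si, sj, symmetric=symmetric)

    def predict_many(self, examples: Sequence[Example]) -> tuple[np.ndarray, np.ndarray]:
        """Scores P(positive) and hard labels for a list of examples."""
        scores = np.array(
            [self.predict(si, sj).p_positive for si, sj, _ in examples]
        )
        return scores, (scores > 0.5).astype(int)

    def evaluate(self, examples: Sequence[Example]) -> MetricsReport:
        """Full metric report (threshold 0.5 plus ROC/PR areas)."""
        labels = np.array([lab for _, _, lab in examples])
        scores, preds = self.predict_many(examples)
        return full_report(labels, scores, preds)

    def summary(self) -> str:
        cfg = self.model_spec.config
        n = len(self.model_spec.examples)
        n_pos = sum(1 for _, _, lab in self.model_spec.examples if lab == 1)
        lines = [
            "InferSent_PN fit summary",
            "=" * 40,
            f"training examples     {n} ({n_pos} pos / {n - n_pos} neg)",
            f"term-vector dim       {cfg.embed_dim}",
            f"encoder               conv{list(cfg.conv_channels)} k={cfg.kernel_size}, max-pool",
            f"sentence embedding    {cfg.sentence_dim}",
            f"classifier hidden     {cfg.hidden_dim} (dropout {cfg.dropout})",
            f"optimiser             Adam lr={cfg.lr}, batch={cfg.batch_size}, epochs={cfg.epochs}",
            f"seed                  {cfg.seed}",
            f"loss first -> final   {self.loss_log[0]:.4f} -> {self.loss_log[-1]:.4f}",
        ]
        return "\n".join(lines)
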