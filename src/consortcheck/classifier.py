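"""Multi-label sentence classification for CONSORT checklist items.

Architecture: a pluggable text *encoder* maps an assembled input (one or
three header-prefixed segments plus an optional position feature) to a
pooled fixed-width vector; a fully connected head standardizes that pooled
representation against training-set feature statistics, concatenates a
learned sentence-position embedding when position features are enabled,
applies dropout, and produces one sigmoid output per checklist item
(multi-label).  Standardization puts rare but informative coordinates on
the same footing as frequent ones, which is what lets the head learn the
scarce checklist items within its fixed training schedule.  The loss is mean binary
cross-entropy over the label dimension, optimized with AdamW (decoupled
weight decay) using two learning-rate groups: the encoder rate (1e-5) for
trainable encoder parameters and the head rate (1e-3) for the fully
connected layer and position embedding.  Defaults follow batch size 4,
dropout 0.1, and a fixed 20 training epochs with no scheduler or early
stopping.

Two encoders are available through ``encoder_id``:

* ``"reference"`` — a deterministic hashed bag-of-tokens embedder with no
  trainable parameters.  It hashes ``(segment role, token)`` pairs into a
  fixed-width signed feature vector, so the whole pipeline is fast,
  dependency-light and exactly seed-reproducible.
* any other id — treated as a pretrained transformer checkpoint name and
  resolved through the optional ``transformers`` backend; a clear
  configuration error is raised when that backend is not installed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .corpus_io import Article, SentenceRecord
from .representation import (
    ABSOLUTE_POSITION_CAP,
    N_RELATIVE_BINS,
    EncoderInput,
    assemble_input,
    build_context_window,
    truncate_segments,
)
from .schema import items_for_section_group, sentence_level_items


class ConfigurationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters and representation settings for one model."""

    encoder_id: str = "reference"
    label_set: tuple[str, ...] = ()
    context: bool = True
    header_mode: str = "all"
    position_kind: str = "none"
    batch_size: int = 4
    encoder_learning_rate: float = 1e-5
    head_learning_rate: float = 1e-3
    dropout: float = 0.1
    epochs: int = 20
    threshold: float = 0.5
    weight_decay: float = 0.01
    max_tokens: int = 512
    encoder_dim: int = 4096
    position_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.label_set:
            self.label_set = tuple(it.code for it in sentence_level_items())
        if len(set(self.label_set)) != len(self.label_set):
            raise ValueError("label_set contains duplicates")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.encoder_learning_rate <= 0 or self.head_learning_rate <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class SentencePrediction:
    article_id: str
    sentence_index: int
    label_set: tuple[str, ...]
    probabilities: np.ndarray
    predicted_labels: set[str]


# --------------------------------------------------------------------------
# Encoder contract
# --------------------------------------------------------------------------

class Encoder(Protocol):
    """Maps an assembled input to a pooled fixed-width representation."""

    dim: int

    def encode(self, inp: EncoderInput) -> np.ndarray: ...


def _tokenize(text: str) -> list[str]:
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


class HashedBagOfTokensEncoder:
    """Deterministic reference encoder.

    Each distinct ``(segment role, token)`` pair lights up *two*
    coordinates of a ``dim``-wide presence vector, chosen by independent
    salted hashes (BLAKE2b) — the duplicate coordinate makes single-slot
    collisions recoverable by a linear head, count-sketch style, and
    presence (rather than signed counts) means collisions can never cancel
    a feature to zero.  Keeping the segment role in the hash lets the head
    distinguish a cue word in the target sentence from the same word in a
    neighbor.  No trainable parameters; hashes are memoized.
    """

    N_HASHES = 2

    def __init__(self, dim: int = 4096):
        self.dim = dim
        self._memo: dict[tuple[str, str], tuple[int, ...]] = {}

    def _coords(self, role: str, token: str) -> tuple[int, ...]:
        key = (role, token)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        coords = tuple(
            int.from_bytes(
                hashlib.blake2b(
                    f"{salt}\x1f{role}\x1f{token}".encode("utf-8"), digest_size=8
                ).digest(),
                "little",
            )
            % self.dim
            for salt in range(self.N_HASHES)
        )
        self._memo[key] = coords
        return coords

    def encode(self, inp: EncoderInput) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        if len(inp.segments) == 1:
            roles = ["target"]
        else:
            roles = ["preceding", "target", "trailing"]
        for role, seg in zip(roles, inp.segments):
            for tok in set(_tokenize(seg)):
                for idx in self._coords(role, tok):
                    vec[idx] = 1.0
        return vec


def resolve_encoder(config: ModelConfig) -> Encoder:
    if config.encoder_id == "reference":
        return HashedBagOfTokensEncoder(dim=config.encoder_dim)
    try:  # pragma: no cover - optional heavy backend
        import transformers  # noqa: F401
    except ImportError as exc:
        raise ConfigurationError(
            f"encoder {config.encoder_id!r} requires the optional "
            "'transformers' backend, which is not installed; use "
            "encoder_id='reference' for the built-in encoder"
        ) from exc
    raise ConfigurationError(  # pragma: no cover
        "pretrained transformer encoders are not wired in this build"
    )


# --------------------------------------------------------------------------
# Instance assembly
# --------------------------------------------------------------------------

@dataclass
class TrainingInstance:
    article_id: str
    sentence_index: int
    inp: EncoderInput
    label_vector: np.ndarray


def build_inputs(
    articles: Sequence[Article], config: ModelConfig
) -> list[tuple[SentenceRecord, EncoderInput]]:
    """Assemble one EncoderInput per sentence, per the model's
    representation settings."""
    out = []
    for art in articles:
        n = art.n_sentences
        for i, rec in enumerate(art.sentences):
            window = build_context_window(art, i)
            inp = assemble_input(
                window,
                header_mode=config.header_mode,
                position_kind=config.position_kind,
                context=config.context,
                index=i,
                n_sentences=n,
            )
            inp = EncoderInput(
                segments=truncate_segments(inp.segments, config.max_tokens),
                position=inp.position,
            )
            out.append((rec, inp))
    return out


def _label_vector(labels: set[str], label_set: Sequence[str]) -> np.ndarray:
    return np.array([1.0 if c in labels else 0.0 for c in label_set])


# --------------------------------------------------------------------------
# Model parameters and forward pass
# --------------------------------------------------------------------------

def _n_positions(position_kind: str) -> int:
    if position_kind == "absolute":
        return ABSOLUTE_POSITION_CAP + 1
    if position_kind == "relative":
        return N_RELATIVE_BINS
    return 0


@dataclass
class TrainedModel:
    """Head parameters plus the training-set feature statistics.

    The pooled representation is standardized (zero mean, unit variance per
    coordinate, statistics estimated on the training set) before the fully
    connected layer; ``feature_mu``/``feature_sd`` are therefore part of the
    model state.
    """

    config: ModelConfig
    label_set: tuple[str, ...]
    W: np.ndarray                      # (in_dim, n_labels)
    b: np.ndarray                      # (n_labels,)
    feature_mu: np.ndarray             # (encoder_dim,)
    feature_sd: np.ndarray             # (encoder_dim,)
    pos_emb: np.ndarray | None = None  # (n_positions, position_dim)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["label_set"] = list(cfg["label_set"])
        (directory / "config.json").write_text(json.dumps(cfg, indent=1))
        arrays = {
            "W": self.W,
            "b": self.b,
            "feature_mu": self.feature_mu,
            "feature_sd": self.feature_sd,
        }
        if self.pos_emb is not None:
            arrays["pos_emb"] = self.pos_emb
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        cfg["label_set"] = tuple(cfg["label_set"])
        config = ModelConfig(**cfg)
        data = np.load(directory / "weights.npz")
        return cls(
            config=config,
            label_set=config.label_set,
            W=data["W"],
            b=data["b"],
            feature_mu=data["feature_mu"],
            feature_sd=data["feature_sd"],
            pos_emb=data["pos_emb"] if "pos_emb" in data else None,
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_features(
    model: TrainedModel, encoded: np.ndarray, positions: np.ndarray | None
) -> np.ndarray:
    standardized = (encoded - model.feature_mu) / model.feature_sd
    if model.pos_emb is not None:
        if positions is None:
            raise ConfigurationError(
                "model was trained with position features but inputs carry none"
            )
        feats = np.hstack([standardized, model.pos_emb[positions]])
    else:
        feats = standardized
    return feats


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

class _AdamW:
    """Decoupled-weight-decay Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lrs: dict[str, float],
                 weight_decay: dict[str, float]):
        self.params = params
        self.lrs = lrs
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            lr = self.lrs[k]
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd[k] * p)


def _encode_all(
    encoder: Encoder, inputs: Sequence[EncoderInput]
) -> tuple[np.ndarray, np.ndarray | None]:
    X = np.stack([encoder.encode(inp) for inp in inputs])
    if any(inp.position is not None for inp in inputs):
        # inputs without a position feature (e.g. augmented instances) embed
        # at index 0
        pos = np.array(
            [inp.position.value if inp.position is not None else 0 for inp in inputs],
            dtype=int,
        )
    else:
        pos = None
    return X, pos


def train(
    articles: Sequence[Article],
    config: ModelConfig,
    extra_instances: Sequence[TrainingInstance] = (),
) -> TrainedModel:
    """Fit the classification head on all sentences of ``articles`` (plus
    optional pre-assembled instances, e.g. augmentation output).

    Reproducible: the same articles, config and seed yield bitwise-identical
    parameters.
    """
    encoder = resolve_encoder(config)
    pairs = build_inputs(articles, config)
    inputs = [inp for _, inp in pairs]
    labels = [_label_vector(rec.labels, config.label_set) for rec, _ in pairs]
    for inst in extra_instances:
        if len(inst.inp.segments) != (3 if config.context else 1):
            raise ConfigurationError(
                "extra instance segment count does not match config.context"
            )
        inputs.append(inst.inp)
        labels.append(inst.label_vector)
    if not inputs:
        raise ValueError("training set is empty")
    for rec, _ in pairs:
        unknown = rec.labels - set(config.label_set)
        if unknown:
            raise ValueError(
                f"record {rec.article_id}:{rec.sentence_index} carries labels "
                f"outside the model label_set: {sorted(unknown)}"
            )

    X, pos = _encode_all(encoder, inputs)
    Y = np.stack(labels)
    # standardize the pooled representation on training statistics;
    # constant coordinates pass through unscaled
    feature_mu = X.mean(axis=0)
    feature_sd = X.std(axis=0)
    feature_sd[feature_sd < 1e-8] = 1.0
    X = (X - feature_mu) / feature_sd
    n, d = X.shape
    L = len(config.label_set)
    n_pos = _n_positions(config.position_kind)
    pdim = config.position_dim if n_pos else 0

    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {
        "W": rng.normal(0.0, 0.02, size=(d + pdim, L)),
        "b": np.zeros(L),
    }
    lrs = {"W": config.head_learning_rate, "b": config.head_learning_rate}
    wd = {"W": config.weight_decay, "b": 0.0}
    if n_pos:
        params["pos_emb"] = rng.normal(0.0, 0.02, size=(n_pos, pdim))
        lrs["pos_emb"] = config.head_learning_rate
        wd["pos_emb"] = 0.0
    opt = _AdamW(params, lrs, wd)

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            if config.dropout > 0:
                mask = (rng.random(xb.shape) >= config.dropout) / (
                    1.0 - config.dropout
                )
                xb = xb * mask
            if n_pos:
                pb = pos[idx]
                feats = np.hstack([xb, params["pos_emb"][pb]])
            else:
                feats = xb
            logits = feats @ params["W"] + params["b"]
            probs = _sigmoid(logits)
            # d(mean BCE)/dlogits, averaged over batch and labels
            dlogits = (probs - Y[idx]) / (len(idx) * L)
            grads = {
                "W": feats.T @ dlogits,
                "b": dlogits.sum(axis=0),
            }
            if n_pos:
                dfeats = dlogits @ params["W"].T
                demb = dfeats[:, d:]
                g_emb = np.zeros_like(params["pos_emb"])
                np.add.at(g_emb, pb, demb)
                grads["pos_emb"] = g_emb
            opt.step(grads)

    return TrainedModel(
        config=config,
        label_set=config.label_set,
        W=params["W"],
        b=params["b"],
        feature_mu=feature_mu,
        feature_sd=feature_sd,
        pos_emb=params.get("pos_emb"),
    )


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------

def binarize(
    probabilities: np.ndarray, threshold: float, label_set: Sequence[str]
) -> set[str]:
    """Labels whose probability meets the threshold (``>=``)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return {c for c, p in zip(label_set, probabilities) if p >= threshold}


def predict(
    model: TrainedModel, articles: Sequence[Article]
) -> list[SentencePrediction]:
    """One prediction per sentence of each article."""
    encoder = resolve_encoder(model.config)
    pairs = build_inputs(articles, model.config)
    if not pairs:
        return []
    X, pos = _encode_all(encoder, [inp for _, inp in pairs])
    feats = _forward_features(model, X, pos)
    probs = _sigmoid(feats @ model.W + model.b)
    out = []
    for (rec, _), pvec in zip(pairs, probs):
        out.append(
            SentencePrediction(
                article_id=rec.article_id,
                sentence_index=rec.sentence_index,
                label_set=model.label_set,
                probabilities=pvec,
                predicted_labels=binarize(
                    pvec, model.config.threshold, model.label_set
                ),
            )
        )
    return out


# --------------------------------------------------------------------------
# Section-specific models
# --------------------------------------------------------------------------

_SECTION_HEADER_GROUP = {
    "methods": "Methods",
    "materials and methods": "Methods",
    "patients and methods": "Methods",
    "subjects and methods": "Methods",
    "results": "Results",
    "discussion": "Discussion",
    "introduction": "Introduction",
    "background": "Introduction",
}


def section_group_of(record: SentenceRecord) -> str | None:
    """Map a sentence's outermost section header to a checklist section
    group (None when unrecognized)."""
    if not record.section_path:
        return None
    return _SECTION_HEADER_GROUP.get(record.section_path[0].strip().lower())


def train_section_specific(
    articles: Sequence[Article], group: str, config: ModelConfig
) -> TrainedModel:
    """Train a model restricted to one section's sentences and labels.

    Supported groups: Methods, Results, Discussion.  An Introduction-specific
    model is deliberately unsupported — the section carries a single relevant
    label (2b, Objectives), so a dedicated model adds nothing.
    """
    if group == "Introduction":
        raise ValueError(
            "Introduction-specific models are not supported (single relevant "
            "label 2b)"
        )
    if group not in {"Methods", "Results", "Discussion"}:
        raise ValueError(f"unsupported section group: {group!r}")
    label_set = tuple(it.code for it in items_for_section_group(group))
    sub_articles = []
    for art in articles:
        keep = [
            rec for rec in art.body_sentences if section_group_of(rec) == group
        ]
        if not keep:
            continue
        sub = Article(article_id=art.article_id, title=art.title)
        for j, rec in enumerate(keep):
            sub.body_sentences.append(
                SentenceRecord(
                    article_id=rec.article_id,
                    sentence_index=j,
                    section_path=list(rec.section_path),
                    text=rec.text,
                    labels=rec.labels & set(label_set),
                    part=rec.part,
                )
            )
        sub_articles.append(sub)
    cfg = ModelConfig(**{**asdict(config), "label_set": label_set})
    return train(sub_articles, cfg)


# --------------------------------------------------------------------------
# Prompt construction for in-context learning, and the generative sequence
# format
# --------------------------------------------------------------------------

ICL_TASK_DESCRIPTION = (
    "You will be given the full text of a randomized controlled trial "
    "publication, sentence by sentence. For each sentence, decide which of "
    "the CONSORT checklist items listed below the sentence reports, if any. "
    "Answer with the item codes for each sentence; answer 'none' when a "
    "sentence reports no item."
)


def build_icl_prompt(
    article: Article,
    items: Sequence,
    shots: int = 0,
    example_pool: Sequence[tuple[str, str]] = (),
) -> str:
    """Deterministic in-context-learning prompt: task description, checklist
    item descriptions, ``shots`` worked examples (0, 1 or 5), then the entire
    article.  Examples are (sentence, answer) pairs drawn in order from
    ``example_pool``."""
    if shots not in (0, 1, 5):
        raise ValueError("shots must be 0, 1 or 5")
    if shots > len(example_pool):
        raise ValueError(
            f"example pool has {len(example_pool)} items, {shots} required"
        )
    parts = [ICL_TASK_DESCRIPTION, "", "Checklist items:"]
    for it in items:
        parts.append(f"{it.code}: {it.title}. {it.description}")
    if shots:
        parts.append("")
        parts.append("Examples:")
        for sent, answer in list(example_pool)[:shots]:
            parts.append(f"Sentence: {sent}")
            parts.append(f"Items: {answer}")
    parts.append("")
    parts.append("Article:")
    for rec in article.sentences:
        parts.append(f"[{rec.sentence_index}] {rec.text}")
    return "\n".join(parts)


GENERATIVE_SEQUENCE_TEMPLATE = "{sentence}. This sentence describes {label}"


def format_generative_sequence(sentence_with_headers: str, label: str) -> str:
    """Sequence-classification-as-generation format:
    ``[SENTENCE]. This sentence describes [LABEL]``."""
    if not label:
        raise ValueError("label must be non-empty")
    return GENERATIVE_SEQUENCE_TEMPLATE.format(
        sentence=sentence_with_headers, label=label
    )


def parse_generative_sequence(sequence: str) -> tuple[str, str]:
    """Inverse of :func:`format_generative_sequence`."""
    marker = ". This sentence describes "
    if marker not in sequence:
        raise ValueError("not a generative classification sequence")
    sentence, label = sequence.rsplit(marker, 1)
    return sentence, label
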