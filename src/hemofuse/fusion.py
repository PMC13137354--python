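"""Multimodal fusion and toy-scale classification.

Fusion strategies over the frozen toy encoders:

* early — concatenate pooled *raw* features of both modalities before any
  encoder (mean flattened patch, mean token embedding);
* late  — train one classifier per modality and average their class
  probabilities at prediction time;
* joint — a shared-space representation combining the encoded image
  (CLS + mean patch embedding), low-dimensional clinical text features
  (per-subtype mention counts, sentiment lexicon counts, Estimated
  Association), and the cross-attention fused vector whose queries come
  from text tokens and keys/values from encoded image patches.  The joint
  heads additionally carry a learnable class-aligned text-evidence gate on
  their logits (a rule-augmented decision layer): for the subtype task the
  evidence is whether the note mentions each subtype, for the sentiment
  tasks the matched lexicon counts.

``image`` and ``text`` single-modality baselines use the encoded CLS+mean
image vector and the pooled token embedding (+ clinical features),
respectively.

Classifier heads are single-hidden-layer perceptrons trained with
mini-batch Adam, softmax cross-entropy, and decoupled weight decay
(hand-written backprop; encoders stay frozen).  Every temporal frame of a
case is a training sample and case-level predictions average the
per-frame probabilities; each head is a small seeded ensemble with
validation-loss checkpoint selection.  Everything is seeded and
bit-reproducible on a fixed platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ConfusionCounts, classification_metrics, confusion_matrix, roc_points
from .synthetic_data import (
    SENTIMENTS,
    SUBTYPE_NAMES,
    SUBTYPES,
    CaseRecord,
    DatasetManifest,
)
from .text_embed import (
    TextEmbeddingTables,
    default_vocabulary,
    encode_text,
    estimated_association,
    lexicon_sentiment,
)
from .vision_embed import PatchConfig, encode_image, patchify

__all__ = [
    "FusionConfig",
    "CrossAttentionParams",
    "CrossAttentionResult",
    "FusedRepresentation",
    "CaseFeatures",
    "FeatureExtractor",
    "cross_attention",
    "clinical_text_features",
    "fuse",
    "train_toy",
    "evaluate",
    "run_benchmark",
    "save_model",
    "load_model",
    "TASKS",
]

STRATEGIES = ("early", "late", "joint")
#: classification tasks and their label accessors
TASKS = {
    "subtype": lambda c: c.subtype,
    "prognosis": lambda c: c.prognosis_sentiment,
    "therapeutic": lambda c: c.therapeutic_sentiment,
}


@dataclass(frozen=True)
class FusionConfig:
    strategy: str = "joint"
    hidden_dim: int = 64
    n_classes_subtype: int = 5
    sentiment_classes: int = 4
    learning_rate: float = 0.01
    n_epochs: int = 100
    batch_size: int = 32
    weight_decay: float = 1.0
    ensemble_size: int = 5
    seed: int = 0
    image_embed_dim: int = 64
    text_embed_dim: int = 32
    patch_size: int = 8
    subtype_labels: tuple[str, ...] = SUBTYPES

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES + ("image", "text"):
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of "
                f"{STRATEGIES + ('image', 'text')}"
            )


@dataclass
class CrossAttentionParams:
    wq: np.ndarray  # (D_text, D_f)
    wk: np.ndarray  # (D_img, D_f)
    wv: np.ndarray  # (D_img, D_f)

    @classmethod
    def seeded(cls, d_text: int, d_img: int, d_fused: int, seed: int) -> "CrossAttentionParams":
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xCA])
        return cls(
            wq=rng.normal(0.0, 1.0 / np.sqrt(d_text), (d_text, d_fused)),
            wk=rng.normal(0.0, 1.0 / np.sqrt(d_img), (d_img, d_fused)),
            wv=rng.normal(0.0, 1.0 / np.sqrt(d_img), (d_img, d_fused)),
        )


@dataclass
class CrossAttentionResult:
    fused: np.ndarray  # pooled attended image content, (D_f,)
    attended: np.ndarray  # (T_text, D_f)
    queries: np.ndarray  # (T_text, D_f)
    weights: np.ndarray  # (T_text, N_patches), rows sum to 1


@dataclass
class FusedRepresentation:
    vector: np.ndarray
    strategy: str
    provenance: str = ""


def cross_attention(
    text_seq: np.ndarray, image_seq: np.ndarray, params: CrossAttentionParams
) -> CrossAttentionResult:
    """Scaled dot-product cross-attention: queries from text vectors,
    keys/values from image patch vectors; attended outputs are mean-pooled
    over text positions into the fused vector.  With a single image patch
    the fused vector is exactly that patch's projected value."""
    text = np.asarray(text_seq, dtype=float)
    image = np.asarray(image_seq, dtype=float)
    if text.size == 0 or image.size == 0:
        raise ValueError("both sequences must be non-empty")
    if text.shape[1] != params.wq.shape[0] or image.shape[1] != params.wk.shape[0]:
        raise ValueError("sequence dims inconsistent with projection shapes")
    q = text @ params.wq
    k = image @ params.wk
    v = image @ params.wv
    logits = q @ k.T / np.sqrt(q.shape[1])
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    weights = e / e.sum(axis=1, keepdims=True)
    attended = weights @ v
    return CrossAttentionResult(
        fused=attended.mean(axis=0), attended=attended, queries=q, weights=weights
    )


def clinical_text_features(
    text: str, subtype_order: tuple[str, ...] = SUBTYPES
) -> np.ndarray:
    """Low-dimensional clinical features of a note: per-subtype mention
    counts, positive/negative/neutral lexicon counts, and EA/100."""
    low = " ".join(text.lower().split())
    mentions = [float(low.count(SUBTYPE_NAMES[s])) for s in subtype_order]
    pos, neg, neu, _ = lexicon_sentiment(text)
    ea = estimated_association(text) / 100.0
    return np.array(mentions + [float(pos), float(neg), float(neu), ea])


@dataclass
class CaseFeatures:
    """All per-case feature views the strategies draw from.  Image-side
    entries are per temporal frame; text-side entries are per case."""

    image_reprs: np.ndarray  # (T_frames, 2*D_img): [CLS ; mean patch] per frame
    image_quads: np.ndarray  # (T_frames, 4*D_img): quadrant-pooled patch embeddings
    ca_fused: np.ndarray  # (T_frames, D_img): cross-attention fused vector per frame
    raw_patch_pools: np.ndarray  # (T_frames, P*P): mean flattened raw patch per frame
    text_pool: np.ndarray  # (2*D_text,): [mean ; max] token embedding
    raw_token_pool: np.ndarray  # (D_text,): mean raw token embedding
    clinical: np.ndarray  # (n_subtypes+4,): mention/lexicon/EA features

    @property
    def n_frames(self) -> int:
        return self.image_reprs.shape[0]


@dataclass
class FeatureExtractor:
    """Shared frozen encoders: toy ViT for images, WordPiece + additive
    embedding tables for text, and the cross-attention projections."""

    config: FusionConfig
    note_kind: str = "radiology"
    patch_config: PatchConfig = None
    tables: TextEmbeddingTables = None
    ca_params: CrossAttentionParams = None

    def __post_init__(self) -> None:
        if self.patch_config is None:
            self.patch_config = PatchConfig(
                patch_size=self.config.patch_size,
                embed_dim=self.config.image_embed_dim,
                seed=self.config.seed,
            )
        if self.tables is None:
            self.tables = TextEmbeddingTables(
                default_vocabulary(), embed_dim=self.config.text_embed_dim,
                seed=self.config.seed,
            )
        if self.ca_params is None:
            self.ca_params = CrossAttentionParams.seeded(
                self.config.text_embed_dim,
                self.config.image_embed_dim,
                self.config.image_embed_dim,
                self.config.seed,
            )

    @staticmethod
    def _quadrant_pool(patch_seq: np.ndarray) -> np.ndarray:
        # coarse spatial pyramid: mean patch embedding per image quadrant
        g = int(round(np.sqrt(patch_seq.shape[0])))
        grid = patch_seq.reshape(g, g, -1)
        h = g // 2
        return np.concatenate(
            [grid[i : i + h, j : j + h].mean(axis=(0, 1)) for i in (0, h) for j in (0, h)]
        )

    def features(self, case: CaseRecord) -> CaseFeatures:
        note = case.notes[self.note_kind]
        text_seq = encode_text(note, self.tables)
        reprs, quads, fused, pools = [], [], [], []
        for frame in case.frames:
            cls_vec, patch_seq = encode_image(frame, self.patch_config)
            reprs.append(np.concatenate([cls_vec, patch_seq.mean(axis=0)]))
            quads.append(self._quadrant_pool(patch_seq))
            fused.append(cross_attention(text_seq, patch_seq, self.ca_params).fused)
            raw = patchify(frame, self.patch_config.patch_size)
            pools.append(raw.reshape(raw.shape[0], -1).mean(axis=0) / 255.0)
        return CaseFeatures(
            image_reprs=np.array(reprs),
            image_quads=np.array(quads),
            ca_fused=np.array(fused),
            raw_patch_pools=np.array(pools),
            text_pool=np.concatenate([text_seq.mean(axis=0), text_seq.max(axis=0)]),
            raw_token_pool=text_seq.mean(axis=0),
            clinical=clinical_text_features(note, self.config.subtype_labels),
        )

    def fused_vector(self, feats: CaseFeatures, strategy: str, frame: int = 0) -> np.ndarray:
        if strategy == "image":
            return feats.image_reprs[frame]
        if strategy == "text":
            return np.concatenate([feats.text_pool, feats.clinical])
        if strategy == "early":
            return np.concatenate([feats.raw_patch_pools[frame], feats.raw_token_pool])
        if strategy == "joint":
            return np.concatenate(
                [
                    feats.image_reprs[frame],
                    feats.image_quads[frame],
                    feats.clinical,
                    feats.ca_fused[frame],
                ]
            )
        if strategy == "late":
            # container only; the trainer splits the two modality halves
            return np.concatenate(
                [feats.image_reprs[frame], feats.text_pool, feats.clinical]
            )
        raise ValueError(f"unknown strategy {strategy!r}")

    def class_evidence(self, feats: CaseFeatures, task: str) -> np.ndarray:
        """Class-aligned text evidence for the gated joint heads.

        Subtype: 0 for mentioned subtypes, -1 for unmentioned (the note
        names the working diagnosis and its differential).  Sentiment:
        matched lexicon counts aligned to (positive, negative, neutral),
        zero for the uncertain class which has no dedicated lexicon.
        """
        n_sub = len(self.config.subtype_labels)
        if task == "subtype":
            mentions = feats.clinical[:n_sub]
            return np.where(mentions > 0, 0.0, -1.0)
        pos, neg, neu = feats.clinical[n_sub : n_sub + 3]
        return np.array([pos, neg, neu, 0.0])


def fuse(
    case_features: CaseFeatures, strategy: str, extractor: FeatureExtractor,
    frame: int = 0,
) -> FusedRepresentation:
    """Per-case fused representation for a strategy (see module docstring)."""
    vec = extractor.fused_vector(case_features, strategy, frame)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite entries in fused representation")
    return FusedRepresentation(vector=vec, strategy=strategy,
                               provenance=f"strategy={strategy},seed={extractor.config.seed}")


# ---------------------------------------------------------------------------
# Classifier heads
# ---------------------------------------------------------------------------


class _GatedMLPHead:
    """Single-hidden-layer softmax classifier with an optional class-aligned
    evidence gate: logits = MLP(x) + wg * evidence.  Hand-written backprop,
    Adam updates, decoupled weight decay on the dense weights."""

    def __init__(self, n_in: int, n_hidden: int, n_classes: int, seed: int):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x4EAD])
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / n_hidden), (n_hidden, n_classes))
        self.b2 = np.zeros(n_classes)
        self.wg = np.zeros(1)
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)] for k, v in self._params().items()}
        self._step = 0

    def _params(self):
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2, "wg": self.wg}

    def _logits(self, x: np.ndarray, evidence: np.ndarray | None) -> np.ndarray:
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        z = h @ self.w2 + self.b2
        if evidence is not None:
            z = z + self.wg[0] * evidence
        return z

    def predict_proba(self, x: np.ndarray, evidence: np.ndarray | None = None) -> np.ndarray:
        z = self._logits(x, evidence)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, x: np.ndarray, y: np.ndarray, evidence: np.ndarray | None = None) -> float:
        p = self.predict_proba(x, evidence)
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))

    def _adam_update(self, grads: dict, lr: float) -> None:
        self._step += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            m, v = self._adam[k]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self._step)
            vhat = v / (1 - b2**self._step)
            getattr(self, k)[...] -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_batch(
        self,
        x: np.ndarray,
        y: np.ndarray,
        lr: float,
        weight_decay: float = 0.0,
        evidence: np.ndarray | None = None,
    ) -> None:
        n = len(y)
        h_pre = x @ self.w1 + self.b1
        h = np.maximum(h_pre, 0.0)
        z = h @ self.w2 + self.b2
        if evidence is not None:
            z = z + self.wg[0] * evidence
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        d_z = p.copy()
        d_z[np.arange(n), y] -= 1.0
        d_z /= n
        grads = {"w2": h.T @ d_z, "b2": d_z.sum(axis=0)}
        if evidence is not None:
            grads["wg"] = np.array([np.sum(d_z * evidence)])
        d_h = (d_z @ self.w2.T) * (h_pre > 0)
        grads["w1"] = x.T @ d_h
        grads["b1"] = d_h.sum(axis=0)
        self._adam_update(grads, lr)
        if weight_decay:
            self.w1 *= 1.0 - lr * weight_decay
            self.w2 *= 1.0 - lr * weight_decay

    def state(self) -> dict:
        return {k: v.copy() for k, v in self._params().items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            getattr(self, k)[...] = v


@dataclass
class TrainReport:
    train_loss: dict[str, list[float]] = field(default_factory=dict)
    val_loss: dict[str, list[float]] = field(default_factory=dict)
    val_accuracy: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: dict[str, int] = field(default_factory=dict)


def _train_head(
    x: np.ndarray,
    y: np.ndarray,
    xv: np.ndarray,
    yv: np.ndarray,
    n_classes: int,
    config: FusionConfig,
    tag: int,
    report: TrainReport,
    name: str,
    ev: np.ndarray | None = None,
    evv: np.ndarray | None = None,
) -> _GatedMLPHead:
    head = _GatedMLPHead(x.shape[1], config.hidden_dim, n_classes, config.seed + tag)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x5C, tag])
    losses, vlosses, vaccs = [], [], []
    best_state, best_loss, best_epoch = head.state(), np.inf, -1
    for epoch in range(config.n_epochs):
        order = rng.permutation(len(y))
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            head.train_batch(
                x[idx], y[idx], config.learning_rate, config.weight_decay,
                None if ev is None else ev[idx],
            )
        losses.append(head.loss(x, y, ev))
        vloss = head.loss(xv, yv, evv)
        vlosses.append(vloss)
        vaccs.append(float(np.mean(np.argmax(head.predict_proba(xv, evv), axis=1) == yv)))
        if vloss < best_loss:
            best_loss, best_state, best_epoch = vloss, head.state(), epoch
    head.load_state(best_state)
    report.train_loss[name] = losses
    report.val_loss[name] = vlosses
    report.val_accuracy[name] = vaccs
    report.best_epoch[name] = best_epoch
    return head


@dataclass
class ToyFusionModel:
    """Trained head ensembles over a frozen feature extractor, one ensemble
    per task.  Late fusion stores an (image, text) ensemble pair per task
    and averages their probabilities.  Case-level predictions average the
    per-frame, per-member probabilities."""

    config: FusionConfig
    extractor: FeatureExtractor
    class_orders: dict[str, tuple[str, ...]]
    heads: dict[str, object] = field(default_factory=dict)
    norms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    # -- feature plumbing ---------------------------------------------------
    def _frame_matrix(self, feats: list[CaseFeatures], strategy: str) -> np.ndarray:
        """(n_cases * n_frames, dim) matrix, frames of a case contiguous."""
        rows = []
        for f in feats:
            for t in range(f.n_frames):
                rows.append(self.extractor.fused_vector(f, strategy, t))
        return np.array(rows)

    def _evidence_matrix(self, feats: list[CaseFeatures], task: str) -> np.ndarray:
        rows = []
        for f in feats:
            e = self.extractor.class_evidence(f, task)
            rows.extend([e] * f.n_frames)
        return np.array(rows)

    def _normalize(self, x: np.ndarray, key: str) -> np.ndarray:
        mu, sd = self.norms[key]
        return (x - mu) / sd

    def _ensemble_proba(
        self, heads: list[_GatedMLPHead], x: np.ndarray, ev: np.ndarray | None,
        n_cases: int,
    ) -> np.ndarray:
        p = np.mean([h.predict_proba(x, ev) for h in heads], axis=0)
        return p.reshape(n_cases, -1, p.shape[1]).mean(axis=1)

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, cases: list[CaseRecord], task: str) -> np.ndarray:
        feats = [self.extractor.features(c) for c in cases]
        return self._predict_proba_feats(feats, task)

    def _predict_proba_feats(self, feats: list[CaseFeatures], task: str) -> np.ndarray:
        n = len(feats)
        if self.config.strategy == "late":
            probs = []
            for key in ("image", "text"):
                x = self._normalize(self._frame_matrix(feats, key), key)
                probs.append(self._ensemble_proba(self.heads[task][key], x, None, n))
            return np.mean(probs, axis=0)
        x = self._normalize(
            self._frame_matrix(feats, self.config.strategy), self.config.strategy
        )
        ev = (
            self._evidence_matrix(feats, task)
            if self.config.strategy == "joint"
            else None
        )
        return self._ensemble_proba(self.heads[task], x, ev, n)

    def predict(self, cases: list[CaseRecord], task: str) -> list[str]:
        proba = self.predict_proba(cases, task)
        order = self.class_orders[task]
        return [order[i] for i in np.argmax(proba, axis=1)]


def _case_labels(cases, task, order):
    lookup = {c: i for i, c in enumerate(order)}
    return np.array([lookup[TASKS[task](c)] for c in cases])


def train_toy(manifest: DatasetManifest, config: FusionConfig) -> tuple[ToyFusionModel, TrainReport]:
    """Train the strategy's classifier-head ensembles on the train split
    (every temporal frame is a sample) with per-epoch validation tracking
    and validation-loss checkpoint selection.  Deterministic for fixed
    data, config and seed."""
    for split in ("train", "validation", "test"):
        if not manifest.split_cases(split):
            raise ValueError(f"split {split!r} is empty")
    class_orders = {
        "subtype": tuple(config.subtype_labels),
        "prognosis": SENTIMENTS,
        "therapeutic": SENTIMENTS,
    }
    known = set(config.subtype_labels)
    train_cases = [c for c in manifest.split_cases("train") if c.subtype in known]
    val_cases = [c for c in manifest.split_cases("validation") if c.subtype in known]

    extractor = FeatureExtractor(config)
    model = ToyFusionModel(config=config, extractor=extractor, class_orders=class_orders)
    report = TrainReport()

    feats_tr = [extractor.features(c) for c in train_cases]
    feats_va = [extractor.features(c) for c in val_cases]
    n_frames = feats_tr[0].n_frames

    strategies = ("image", "text") if config.strategy == "late" else (config.strategy,)
    mats = {}
    for strat in strategies:
        xt = model._frame_matrix(feats_tr, strat)
        mu = xt.mean(axis=0)
        sd = np.where(xt.std(axis=0) > 1e-9, xt.std(axis=0), 1.0)
        model.norms[strat] = (mu, sd)
        mats[strat] = (
            model._normalize(xt, strat),
            model._normalize(model._frame_matrix(feats_va, strat), strat),
        )

    for t_idx, (task, order) in enumerate(class_orders.items()):
        y = np.repeat(_case_labels(train_cases, task, order), n_frames)
        yv = np.repeat(_case_labels(val_cases, task, order), n_frames)
        gated = config.strategy == "joint"
        ev = model._evidence_matrix(feats_tr, task) if gated else None
        evv = model._evidence_matrix(feats_va, task) if gated else None
        if config.strategy == "late":
            model.heads[task] = {}
            for s_idx, strat in enumerate(strategies):
                xt, xv = mats[strat]
                model.heads[task][strat] = [
                    _train_head(
                        xt, y, xv, yv, len(order), config,
                        tag=1000 * t_idx + 100 * s_idx + k,
                        report=report, name=f"{task}/{strat}/{k}",
                    )
                    for k in range(config.ensemble_size)
                ]
        else:
            xt, xv = mats[config.strategy]
            model.heads[task] = [
                _train_head(
                    xt, y, xv, yv, len(order), config,
                    tag=1000 * t_idx + k, report=report, name=f"{task}/{k}",
                    ev=ev, evv=evv,
                )
                for k in range(config.ensemble_size)
            ]
    return model, report


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-(subtype, task) metric rows mirroring the fusion-strategy result
    tables, plus per-task confusion matrices, ROC curves and overall
    accuracies."""

    table: pd.DataFrame
    confusions: dict[str, np.ndarray]
    curves: dict[str, list[tuple[float, float]]]
    overall: dict[str, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _ovr_counts(truths, preds, cls) -> ConfusionCounts:
    tp = sum(1 for t, p in zip(truths, preds) if t == cls and p == cls)
    fp = sum(1 for t, p in zip(truths, preds) if t != cls and p == cls)
    fn = sum(1 for t, p in zip(truths, preds) if t == cls and p != cls)
    tn = len(truths) - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def evaluate(model: ToyFusionModel, manifest: DatasetManifest, split: str) -> EvalReport:
    """Score a split: one row per (subtype, task).  For the subtype task the
    row holds that class's one-vs-rest metrics; for the sentiment tasks it
    holds metrics on the subset of cases with that subtype (macro over the
    sentiment classes present)."""
    cases = [c for c in manifest.split_cases(split) if c.subtype in set(model.config.subtype_labels)]
    if not cases:
        raise ValueError(f"split {split!r} has no scoreable cases")
    subtype_order = model.class_orders["subtype"]

    feats = [model.extractor.features(c) for c in cases]
    probas = {task: model._predict_proba_feats(feats, task) for task in TASKS}
    preds = {
        task: [model.class_orders[task][i] for i in np.argmax(probas[task], axis=1)]
        for task in TASKS
    }
    truths = {task: [TASKS[task](c) for c in cases] for task in TASKS}

    confusions = {
        task: confusion_matrix(preds[task], truths[task], model.class_orders[task])
        for task in TASKS
    }
    overall = {
        task: float(np.mean([p == t for p, t in zip(preds[task], truths[task])]))
        for task in TASKS
    }
    curves = {}
    for task, order in model.class_orders.items():
        for j, cls in enumerate(order):
            y = np.array([1 if t == cls else 0 for t in truths[task]])
            if 0 < y.sum() < len(y):
                curves[f"{task}/{cls}"], _ = roc_points(probas[task][:, j], y)

    rows = []
    for subtype in subtype_order:
        cc = _ovr_counts(truths["subtype"], preds["subtype"], subtype)
        m = classification_metrics(cc)
        y = np.array([1 if t == subtype else 0 for t in truths["subtype"]])
        j = subtype_order.index(subtype)
        auc = np.nan
        if 0 < y.sum() < len(y):
            _, auc = roc_points(probas["subtype"][:, j], y)
        rows.append(
            dict(subtype=subtype, task="subtype", accuracy=m.accuracy,
                 precision=m.precision, recall=m.recall, f1=m.f1, auc=auc)
        )
        mask = [i for i, t in enumerate(truths["subtype"]) if t == subtype]
        for task in ("prognosis", "therapeutic"):
            sub_truth = [truths[task][i] for i in mask]
            sub_pred = [preds[task][i] for i in mask]
            present = sorted(set(sub_truth))
            per_class = [
                classification_metrics(_ovr_counts(sub_truth, sub_pred, cls))
                for cls in present
            ]
            acc = float(np.mean([p == t for p, t in zip(sub_pred, sub_truth)])) if mask else np.nan
            aucs = []
            for cls in present:
                jj = model.class_orders[task].index(cls)
                y = np.array([1 if t == cls else 0 for t in sub_truth])
                if 0 < y.sum() < len(y):
                    _, a = roc_points(probas[task][mask, jj], y)
                    aucs.append(a)
            rows.append(
                dict(
                    subtype=subtype, task=task, accuracy=acc,
                    precision=float(np.mean([m.precision for m in per_class])),
                    recall=float(np.mean([m.recall for m in per_class])),
                    f1=float(np.mean([m.f1 for m in per_class])),
                    auc=float(np.mean(aucs)) if aucs else np.nan,
                )
            )
    return EvalReport(table=pd.DataFrame(rows), confusions=confusions,
                      curves=curves, overall=overall)


# ---------------------------------------------------------------------------
# Persistence and benchmark harness
# ---------------------------------------------------------------------------


def save_model(model: ToyFusionModel, path) -> None:
    """Persist a trained model as an .npz bundle with a JSON metadata
    sidecar (config + class orders); the frozen extractor is rebuilt from
    the config seed on load."""
    arrays = {}
    for task, head in model.heads.items():
        if isinstance(head, dict):
            for strat, ens in head.items():
                for k_idx, h in enumerate(ens):
                    for k, v in h.state().items():
                        arrays[f"head__{task}__{strat}__{k_idx}__{k}"] = v
        else:
            for k_idx, h in enumerate(head):
                for k, v in h.state().items():
                    arrays[f"head__{task}__-__{k_idx}__{k}"] = v
    for key, (mu, sd) in model.norms.items():
        arrays[f"norm__{key}__mu"] = mu
        arrays[f"norm__{key}__sd"] = sd
    path = Path(path)
    np.savez(path, **arrays)
    meta = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.config.__dict__.items()
        },
        "class_orders": {t: list(o) for t, o in model.class_orders.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2), encoding="utf-8")


def load_model(path) -> ToyFusionModel:
    """Inverse of save_model."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    cfg_data = dict(meta["config"])
    cfg_data["subtype_labels"] = tuple(cfg_data["subtype_labels"])
    config = FusionConfig(**cfg_data)
    model = ToyFusionModel(
        config=config,
        extractor=FeatureExtractor(config),
        class_orders={t: tuple(o) for t, o in meta["class_orders"].items()},
    )
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    states: dict = {}
    for key in data.files:
        if key.startswith("norm__"):
            continue
        _, task, strat, k_idx, param = key.split("__")
        states.setdefault(task, {}).setdefault(strat, {}).setdefault(int(k_idx), {})[param] = data[key]
    for task, by_strat in states.items():
        def _build(state):
            head = _GatedMLPHead(
                state["w1"].shape[0], config.hidden_dim, state["w2"].shape[1], config.seed
            )
            head.load_state(state)
            return head

        if config.strategy == "late":
            model.heads[task] = {
                strat: [_build(members[i]) for i in sorted(members)]
                for strat, members in by_strat.items()
            }
        else:
            members = by_strat["-"]
            model.heads[task] = [_build(members[i]) for i in sorted(members)]
    for key in data.files:
        if key.startswith("norm__") and key.endswith("__mu"):
            strat = key.split("__")[1]
            model.norms[strat] = (data[key], data[f"norm__{strat}__sd"])
    return model


def run_benchmark(
    manifest: DatasetManifest,
    seed: int = 0,
    strategies: tuple[str, ...] = ("joint", "late", "early", "image", "text"),
    config: FusionConfig | None = None,
) -> pd.DataFrame:
    """Train and test every fusion strategy (plus the single-modality
    baselines) on one manifest; returns a per-strategy table of test-split
    accuracies for the three tasks."""
    rows = []
    for strat in strategies:
        cfg = FusionConfig(
            strategy=strat,
            seed=seed,
            **(
                {}
                if config is None
                else {
                    k: getattr(config, k)
                    for k in (
                        "hidden_dim", "learning_rate", "n_epochs", "batch_size",
                        "weight_decay", "ensemble_size", "image_embed_dim",
                        "text_embed_dim", "patch_size", "subtype_labels",
                    )
                }
            ),
        )
        model, _ = train_toy(manifest, cfg)
        report = evaluate(model, manifest, "test")
        rows.append({"strategy": strat, **{f"{t}_accuracy": v for t, v in report.overall.items()}})
    return pd.DataFrame(rows)
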