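"""Evaluation protocol: grouped cross-validation, sentence- and
article-level metrics, and matched-pairs significance testing.

Sentence-level evaluation scores every (sentence, label) binary decision;
micro metrics pool confusion counts over all such units, macro-F1 averages
per-label F1 (labels absent from both gold and predictions have undefined
F1 and are excluded, which matters for rare items in small folds).  AUC is
computed from the predicted probabilities, micro-averaged over pooled
(sentence, label) scores by default.

Two article-level schemes summarize practical screening utility.  *ANY*
asks, per (article, item), whether the model correctly detects that the
article reports the item anywhere.  *1+* additionally requires at least one
predicted supporting sentence to coincide with a gold supporting sentence;
an item flagged in both gold and prediction but with disjoint sentence sets
counts as one false positive and one false negative.

Cross-validation is grouped by article: every sentence of an article shares
its fold, so no article leaks between training and test.  Model comparisons
use McNemar's matched-pairs test on the pooled (sentence, label) decisions,
with the continuity-corrected chi-square statistic for 20+ discordant pairs
and the exact binomial tail below that.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .corpus_io import Article
from .classifier import (
    ModelConfig,
    SentencePrediction,
    TrainingInstance,
    predict,
    train,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Fold planning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignment: dict[str, int]
    seed: int

    def fold_articles(self, articles: Sequence[Article], fold: int) -> list[Article]:
        return [a for a in articles if self.assignment[a.article_id] == fold]

    def train_articles(self, articles: Sequence[Article], fold: int) -> list[Article]:
        return [a for a in articles if self.assignment[a.article_id] != fold]


def group_kfold(articles: Sequence[Article], k: int = 5, seed: int = 0) -> FoldPlan:
    """Partition articles into ``k`` folds: shuffle by seed, deal
    round-robin.  All sentences of an article share its fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(articles) < k:
        raise ValueError(f"need at least {k} articles for {k} folds")
    ids = [a.article_id for a in articles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate article ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: i % k for i, j in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# --------------------------------------------------------------------------
# Confusion counting and reports
# --------------------------------------------------------------------------

@dataclass
class LabelConfusion:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    per_label: dict[str, LabelConfusion]
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_f1: float
    auc: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "auc": self.auc,
            "per_label": {
                c: {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                    "precision": m.precision, "recall": m.recall, "f1": m.f1}
                for c, m in self.per_label.items()
            },
        }


def _report_from_confusions(
    per_label: dict[str, LabelConfusion], auc: float = float("nan")
) -> EvalReport:
    tp = sum(m.tp for m in per_label.values())
    fp = sum(m.fp for m in per_label.values())
    fn = sum(m.fn for m in per_label.values())
    micro_p = tp / (tp + fp) if tp + fp else 0.0
    micro_r = tp / (tp + fn) if tp + fn else 0.0
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    defined = [
        m.f1 for m in per_label.values() if (m.tp + m.fp + m.fn) > 0
    ]
    skipped = len(per_label) - len(defined)
    if skipped:
        logger.debug(
            "macro-F1 excludes %d labels absent from both gold and predictions",
            skipped,
        )
    macro_f1 = float(np.mean(defined)) if defined else 0.0
    return EvalReport(
        per_label=per_label,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f1,
        macro_f1=macro_f1,
        auc=auc,
    )


def _align(
    gold: Sequence, predictions: Sequence[SentencePrediction]
) -> list[tuple]:
    """Align gold sentence records with predictions on
    (article_id, sentence_index)."""
    gold_map = {(g.article_id, g.sentence_index): g for g in gold}
    pred_map = {(p.article_id, p.sentence_index): p for p in predictions}
    if set(gold_map) != set(pred_map):
        missing = set(gold_map) ^ set(pred_map)
        raise ValueError(
            f"gold and predictions are misaligned on {len(missing)} units, "
            f"e.g. {sorted(missing)[:3]}"
        )
    return [(gold_map[k], pred_map[k]) for k in sorted(gold_map)]


def _flatten_gold(gold: Sequence) -> list:
    """Accept either articles or sentence records as gold."""
    out = []
    for g in gold:
        if isinstance(g, Article):
            out.extend(g.sentences)
        else:
            out.append(g)
    return out


def sentence_metrics(
    gold: Sequence,
    predictions: Sequence[SentencePrediction],
    label_set: Sequence[str],
    compute_auc: bool = True,
) -> EvalReport:
    """Sentence-level precision/recall/F1 (micro and macro) and AUC over
    pooled (sentence, label) units."""
    pairs = _align(_flatten_gold(gold), predictions)
    per_label = {c: LabelConfusion() for c in label_set}
    y_true, y_score = [], []
    for g, p in pairs:
        for j, code in enumerate(label_set):
            in_gold = code in g.labels
            in_pred = code in p.predicted_labels
            m = per_label[code]
            if in_gold and in_pred:
                m.tp += 1
            elif in_pred:
                m.fp += 1
            elif in_gold:
                m.fn += 1
            else:
                m.tn += 1
            if compute_auc:
                y_true.append(1 if in_gold else 0)
                y_score.append(float(p.probabilities[j]))
    auc = float("nan")
    if compute_auc and len(set(y_true)) == 2:
        auc = float(roc_auc_score(y_true, y_score))
    return _report_from_confusions(per_label, auc)


def _article_item_sets(
    gold: Sequence, predictions: Sequence[SentencePrediction], label_set: Sequence[str]
) -> dict[str, dict[str, tuple[set[int], set[int]]]]:
    """Per article and item: (gold sentence indices, predicted indices)."""
    pairs = _align(_flatten_gold(gold), predictions)
    by_article: dict[str, dict[str, tuple[set[int], set[int]]]] = {}
    for g, p in pairs:
        entry = by_article.setdefault(
            g.article_id, {c: (set(), set()) for c in label_set}
        )
        for code in label_set:
            if code in g.labels:
                entry[code][0].add(g.sentence_index)
            if code in p.predicted_labels:
                entry[code][1].add(g.sentence_index)
    return by_article


def article_any(
    gold: Sequence,
    predictions: Sequence[SentencePrediction],
    label_set: Sequence[str],
) -> EvalReport:
    """Article-level scheme: an (article, item) unit is correct when the
    model's claim that the article reports the item (anywhere) matches the
    gold annotation."""
    by_article = _article_item_sets(gold, predictions, label_set)
    per_label = {c: LabelConfusion() for c in label_set}
    for entry in by_article.values():
        for code in label_set:
            g_idx, p_idx = entry[code]
            m = per_label[code]
            if g_idx and p_idx:
                m.tp += 1
            elif p_idx:
                m.fp += 1
            elif g_idx:
                m.fn += 1
            else:
                m.tn += 1
    return _report_from_confusions(per_label)


def article_one_plus(
    gold: Sequence,
    predictions: Sequence[SentencePrediction],
    label_set: Sequence[str],
) -> EvalReport:
    """Stricter article-level scheme: a true positive additionally requires
    at least one sentence in common between predicted and gold supporting
    sentences; a both-present unit with no overlap counts as one FP and one
    FN."""
    by_article = _article_item_sets(gold, predictions, label_set)
    per_label = {c: LabelConfusion() for c in label_set}
    for entry in by_article.values():
        for code in label_set:
            g_idx, p_idx = entry[code]
            m = per_label[code]
            if g_idx and p_idx:
                if g_idx & p_idx:
                    m.tp += 1
                else:
                    m.fp += 1
                    m.fn += 1
            elif p_idx:
                m.fp += 1
            elif g_idx:
                m.fn += 1
            else:
                m.tn += 1
    return _report_from_confusions(per_label)


# --------------------------------------------------------------------------
# McNemar matched-pairs comparison
# --------------------------------------------------------------------------

def mcnemar_from_counts(n01: int, n10: int) -> tuple[float, float]:
    """McNemar's test from discordant-pair counts.

    Continuity-corrected chi-square statistic ``(|n01-n10|-1)^2/(n01+n10)``
    with 1 df when the discordant total is at least 20; exact two-sided
    binomial tail below that; p = 1 when there are no discordant pairs.
    """
    n = n01 + n10
    if n == 0:
        return 0.0, 1.0
    if n < 20:
        k = min(n01, n10)
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
        return float("nan"), p
    stat = (abs(n01 - n10) - 1) ** 2 / n
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p


def mcnemar_compare(
    decisions_a: Sequence[bool] | np.ndarray,
    decisions_b: Sequence[bool] | np.ndarray,
    gold: Sequence[bool] | np.ndarray,
) -> tuple[float, float, int, int]:
    """Compare two systems on identical (sentence, label) binary decisions.

    Returns (statistic, p_value, n01, n10) where n01 counts units system A
    got right and B wrong, n10 the reverse.
    """
    a = np.asarray(decisions_a, dtype=bool)
    b = np.asarray(decisions_b, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    if not (a.shape == b.shape == g.shape):
        raise ValueError("decision vectors must align on identical units")
    correct_a = a == g
    correct_b = b == g
    n01 = int(np.sum(correct_a & ~correct_b))
    n10 = int(np.sum(~correct_a & correct_b))
    stat, p = mcnemar_from_counts(n01, n10)
    return stat, p, n01, n10


def decisions_vector(
    gold: Sequence,
    predictions: Sequence[SentencePrediction],
    label_set: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (sentence, label) prediction and gold indicator vectors, in a
    canonical unit order shared by aligned systems."""
    pairs = _align(_flatten_gold(gold), predictions)
    pred, truth = [], []
    for g, p in pairs:
        for code in label_set:
            pred.append(code in p.predicted_labels)
            truth.append(code in g.labels)
    return np.asarray(pred, dtype=bool), np.asarray(truth, dtype=bool)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

@dataclass
class CrossValReport:
    plan: FoldPlan
    sentence_folds: list[EvalReport]
    article_any_folds: list[EvalReport]
    article_one_plus_folds: list[EvalReport]

    def _agg(self, reports: list[EvalReport], attr: str) -> tuple[float, float]:
        vals = [getattr(r, attr) for r in reports]
        return float(np.mean(vals)), float(np.std(vals))

    def summary(self) -> dict:
        out = {}
        for scheme, reports in [
            ("sentence", self.sentence_folds),
            ("article_any", self.article_any_folds),
            ("article_one_plus", self.article_one_plus_folds),
        ]:
            for attr in ("micro_precision", "micro_recall", "micro_f1", "macro_f1"):
                mean, sd = self._agg(reports, attr)
                out[f"{scheme}.{attr}"] = {"mean": mean, "sd": sd}
            if scheme == "sentence":
                aucs = [r.auc for r in reports if not math.isnan(r.auc)]
                if aucs:
                    out["sentence.auc"] = {
                        "mean": float(np.mean(aucs)),
                        "sd": float(np.std(aucs)),
                    }
        return out


def cross_validate(
    articles: Sequence[Article],
    config: ModelConfig,
    plan: FoldPlan | None = None,
    augment_fn: Callable[[Sequence[Article]], Sequence[TrainingInstance]] | None = None,
) -> CrossValReport:
    """Grouped k-fold cross-validation.

    For each fold, a model is trained on the other k-1 folds — plus any
    augmentation instances ``augment_fn`` derives from those training
    articles only — and evaluated on the held-out fold at sentence level and
    under both article-level schemes.  Augmentation leakage is asserted:
    every augmented instance must originate from a training-fold article.
    """
    plan = plan if plan is not None else group_kfold(articles, seed=config.seed)
    label_set = config.label_set
    sent_reports, any_reports, oneplus_reports = [], [], []
    for fold in range(plan.k):
        train_arts = plan.train_articles(articles, fold)
        test_arts = plan.fold_articles(articles, fold)
        if not any(a.n_sentences for a in test_arts):
            raise ValueError(f"fold {fold} has no test sentences")
        extra: Sequence[TrainingInstance] = ()
        if augment_fn is not None:
            extra = augment_fn(train_arts)
            train_ids = {a.article_id for a in train_arts}
            test_ids = {a.article_id for a in test_arts}
            for inst in extra:
                src = inst.article_id.removeprefix("aug:").split(":")[0]
                if src in test_ids and src not in train_ids:
                    raise ValueError(
                        f"augmentation leakage: instance from test article {src}"
                    )
        model = train(train_arts, config, extra_instances=extra)
        preds = predict(model, test_arts)
        sent_reports.append(sentence_metrics(test_arts, preds, label_set))
        any_reports.append(article_any(test_arts, preds, label_set))
        oneplus_reports.append(article_one_plus(test_arts, preds, label_set))
    return CrossValReport(
        plan=plan,
        sentence_folds=sent_reports,
        article_any_folds=any_reports,
        article_one_plus_folds=oneplus_reports,
    )


def label_frequency_baseline(
    train_articles: Sequence[Article],
    test_articles: Sequence[Article],
    label_set: Sequence[str],
    seed: int = 0,
) -> list[SentencePrediction]:
    """Sanity-floor baseline: each label is predicted independently with
    probability equal to its training-set sentence frequency."""
    counts = {c: 0 for c in label_set}
    n = 0
    for art in train_articles:
        for rec in art.sentences:
            n += 1
            for c in rec.labels:
                if c in counts:
                    counts[c] += 1
    freqs = np.array([counts[c] / n if n else 0.0 for c in label_set])
    rng = np.random.default_rng(seed)
    preds = []
    for art in test_articles:
        for rec in art.sentences:
            draws = rng.random(len(label_set)) < freqs
            preds.append(
                SentencePrediction(
                    article_id=rec.article_id,
                    sentence_index=rec.sentence_index,
                    label_set=tuple(label_set),
                    probabilities=freqs.copy(),
                    predicted_labels={
                        c for c, d in zip(label_set, draws) if d
                    },
                )
            )
    return preds
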