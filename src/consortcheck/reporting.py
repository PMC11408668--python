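"""Per-article checklist reports for practical screening.

A report says, for each in-scope checklist item, whether the article
*reports* it — a sentence-level item counts as reported when at least one
sentence is predicted for it (the same presence function the article-level
ANY evaluation uses) — and backs every reported item with its supporting
sentences, ordered by predicted probability.  Items 1a/1b come from the
title/abstract rules with their matched evidence.  Item 2a is shown as
"not assessed": it is deliberately excluded from classification because
virtually every article reports background material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .classifier import SentencePrediction
from .corpus_io import Article
from .rules import ArticleLevelResult
from .schema import load_checklist, _code_sort_key


@dataclass(frozen=True)
class SupportingSentence:
    sentence_index: int
    text: str
    probability: float


@dataclass
class ItemStatus:
    code: str
    title: str
    status: str  # "reported" | "missing" | "not assessed"
    supporting: list[SupportingSentence] = field(default_factory=list)
    evidence: str = ""


@dataclass
class ChecklistReport:
    article_id: str
    items: list[ItemStatus]

    def to_json(self) -> str:
        return json.dumps(
            {
                "article_id": self.article_id,
                "items": [
                    {
                        "code": it.code,
                        "title": it.title,
                        "status": it.status,
                        "evidence": it.evidence,
                        "supporting": [
                            {
                                "sentence_index": s.sentence_index,
                                "text": s.text,
                                "probability": s.probability,
                            }
                            for s in it.supporting
                        ],
                    }
                    for it in self.items
                ],
            },
            indent=1,
        )

    def to_markdown(self) -> str:
        lines = [f"# Checklist report: {self.article_id}", ""]
        for it in self.items:
            mark = {"reported": "x", "missing": " ", "not assessed": "-"}[it.status]
            lines.append(f"- [{mark}] **{it.code}** {it.title}: {it.status}")
            if it.evidence:
                lines.append(f"  - evidence: `{it.evidence}`")
            for s in it.supporting:
                lines.append(
                    f"  - s{s.sentence_index} (p={s.probability:.2f}): {s.text}"
                )
        return "\n".join(lines)


def build_report(
    article: Article,
    predictions: Sequence[SentencePrediction],
    rule_results: ArticleLevelResult | None = None,
) -> ChecklistReport:
    """Assemble the per-article checklist report.

    ``predictions`` must cover every sentence of the article exactly once.
    """
    preds = [p for p in predictions if p.article_id == article.article_id]
    covered = {p.sentence_index for p in preds}
    expected = {rec.sentence_index for rec in article.sentences}
    if covered != expected:
        raise ValueError(
            f"predictions do not cover article {article.article_id}: "
            f"{len(expected - covered)} sentences missing"
        )
    text_of = {rec.sentence_index: rec.text for rec in article.sentences}

    checklist = load_checklist()
    items: list[ItemStatus] = []
    for item in sorted(checklist, key=lambda it: _code_sort_key(it.code)):
        if item.article_level:
            if rule_results is None:
                status = ItemStatus(item.code, item.title, "missing")
            else:
                flag = rule_results.item_1a if item.code == "1a" else rule_results.item_1b
                ev = (
                    rule_results.evidence_1a
                    if item.code == "1a"
                    else rule_results.evidence_1b
                )
                status = ItemStatus(
                    item.code,
                    item.title,
                    "reported" if flag else "missing",
                    evidence=ev,
                )
            items.append(status)
            continue
        if not item.sentence_level:
            items.append(ItemStatus(item.code, item.title, "not assessed"))
            continue
        supporting = []
        for p in preds:
            if item.code in p.predicted_labels:
                j = p.label_set.index(item.code)
                supporting.append(
                    SupportingSentence(
                        sentence_index=p.sentence_index,
                        text=text_of[p.sentence_index],
                        probability=float(p.probabilities[j]),
                    )
                )
        supporting.sort(key=lambda s: (-s.probability, s.sentence_index))
        items.append(
            ItemStatus(
                item.code,
                item.title,
                "reported" if supporting else "missing",
                supporting=supporting,
            )
        )
    return ChecklistReport(article_id=article.article_id, items=items)
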