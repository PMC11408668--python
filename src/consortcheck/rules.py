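"""Rule-based recognition of the two article-level checklist items.

Item 1a asks whether the study is identified as randomized in the title;
item 1b asks whether the abstract is structured.  Both are properties of the
whole article, not of individual sentences, and simple rules recognize them
reliably: a case-insensitive stem search over the title (stems ``random``,
``randomis``, ``randomiz`` — substring matching, so "randomization" and
"randomised" both hit), and a check of whether the abstract opens with a
structured-abstract section label from the National Library of Medicine's
list.  The header list is vendored as a plain-text resource and can be
replaced with a different snapshot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .corpus_io import Article, SentenceRecord

TITLE_STEMS = ("random", "randomis", "randomiz")


class HeaderResourceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ArticleLevelResult:
    article_id: str
    item_1a: bool
    item_1b: bool
    evidence_1a: str = ""
    evidence_1b: str = ""


def check_title_randomized(title: str) -> tuple[bool, str]:
    """Case-insensitive substring search for the randomization stems."""
    lowered = title.strip().lower()
    for stem in TITLE_STEMS:
        if stem in lowered:
            return True, stem
    return False, ""


def load_structured_header_list(path: str | Path | None = None) -> set[str]:
    """The NLM structured-abstract header list: uppercase, deduplicated."""
    if path is None:
        try:
            text = (
                resources.files("consortcheck.data")
                .joinpath("nlm_structured_headers.txt")
                .read_text(encoding="utf-8")
            )
        except (FileNotFoundError, ModuleNotFoundError) as exc:
            raise HeaderResourceError(
                "packaged NLM header list is missing"
            ) from exc
    else:
        p = Path(path)
        if not p.exists():
            raise HeaderResourceError(f"header list not found: {p}")
        text = p.read_text(encoding="utf-8")
    headers = set()
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        headers.add(ln.upper().rstrip(":.").strip())
    if not headers:
        raise HeaderResourceError("header list is empty")
    return headers


def check_structured_abstract(
    abstract_sentences: Sequence[SentenceRecord] | Sequence[str],
    headers: set[str] | None = None,
) -> tuple[bool, str]:
    """True iff the abstract *starts with* a structured-abstract header.

    The leading token sequence (up to the first colon or period) is
    uppercased, stripped of trailing punctuation, and looked up in the NLM
    list; only the first header position is considered.
    """
    if headers is None:
        headers = load_structured_header_list()
    if not abstract_sentences:
        return False, ""
    first = abstract_sentences[0]
    text = first.text if isinstance(first, SentenceRecord) else str(first)
    text = text.lstrip()
    if not text:
        return False, ""
    m = re.split(r"[:.]", text, maxsplit=1)
    candidate = m[0].strip().upper()
    if candidate in headers:
        return True, candidate
    return False, ""


def check_article(
    article: Article, headers: set[str] | None = None
) -> ArticleLevelResult:
    """Evaluate items 1a and 1b for one article."""
    ok_1a, ev_1a = check_title_randomized(article.title)
    ok_1b, ev_1b = check_structured_abstract(article.abstract_sentences, headers)
    return ArticleLevelResult(
        article_id=article.article_id,
        item_1a=ok_1a,
        item_1b=ok_1b,
        evidence_1a=ev_1a,
        evidence_1b=ev_1b,
    )
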