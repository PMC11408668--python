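"""Corpus reading, writing, and descriptive statistics.

The on-disk corpus is one row per sentence with the columns

    article_id, sentence_index, part, section_path, text, labels

where ``part`` is one of ``title``/``abstract``/``body``, ``section_path``
joins nested section headers outermost-first with ``>``, and ``labels`` joins
item codes with ``|`` (empty cell allowed).  Sentence indices are 0-based and
run through title, abstract and body in reading order so a single index
stream feeds the position features.  The same schema is accepted as CSV or
JSON-lines.  Raw JATS-style XML full texts can also be ingested, with
sentence segmentation delegated to a configurable splitter.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from lxml import etree

from .schema import normalize_code, sentence_level_items

CSV_COLUMNS = ["article_id", "sentence_index", "part", "section_path", "text", "labels"]
PARTS = ("title", "abstract", "body")


class CorpusParseError(ValueError):
    """Raised for malformed corpus files."""


@dataclass
class SentenceRecord:
    """One sentence of an RCT publication with optional gold item labels."""

    article_id: str
    sentence_index: int
    section_path: list[str]
    text: str
    labels: set[str] = field(default_factory=set)
    part: str = "body"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("sentence text must be non-empty")
        if self.part not in PARTS:
            raise ValueError(f"part must be one of {PARTS}, got {self.part!r}")


@dataclass
class Article:
    """A publication reconstructed from its sentence rows."""

    article_id: str
    title: str
    abstract_sentences: list[SentenceRecord] = field(default_factory=list)
    body_sentences: list[SentenceRecord] = field(default_factory=list)
    title_sentences: list[SentenceRecord] = field(default_factory=list)

    @property
    def sentences(self) -> list[SentenceRecord]:
        """All sentences in reading order (title, abstract, body)."""
        return self.title_sentences + self.abstract_sentences + self.body_sentences

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class CorpusStats:
    n_articles: int
    n_sentences: int
    n_labeled_sentences: int
    n_label_instances: int
    mean_items_per_article: float


def _valid_codes() -> set[str]:
    return {it.code for it in sentence_level_items()}


def _parse_labels(cell: str, row_no: int, valid: set[str]) -> set[str]:
    if not cell or not str(cell).strip():
        return set()
    labels = set()
    for raw in str(cell).split("|"):
        raw = raw.strip()
        if not raw:
            continue
        code = normalize_code(raw)
        if code not in valid:
            raise CorpusParseError(
                f"row {row_no}: unknown item code {raw!r}"
            )
        labels.add(code)
    return labels


def _rows_to_articles(rows: Iterable[dict], validate_labels: bool = True) -> list[Article]:
    valid = _valid_codes() if validate_labels else None
    articles: dict[str, Article] = {}
    for i, row in enumerate(rows):
        for col in CSV_COLUMNS:
            if col not in row:
                raise CorpusParseError(f"missing required column: {col!r}")
        aid = str(row["article_id"])
        part = str(row["part"])
        path_cell = row["section_path"]
        if path_cell is None or (isinstance(path_cell, float) and pd.isna(path_cell)):
            path_cell = ""
        path = [h for h in str(path_cell).split(">") if h]
        label_cell = row["labels"]
        if label_cell is None or (isinstance(label_cell, float) and pd.isna(label_cell)):
            label_cell = ""
        if validate_labels:
            labels = _parse_labels(label_cell, i, valid)
        else:
            labels = {normalize_code(x) for x in str(label_cell).split("|") if x.strip()}
        rec = SentenceRecord(
            article_id=aid,
            sentence_index=int(row["sentence_index"]),
            section_path=path,
            text=str(row["text"]),
            labels=labels,
            part=part,
        )
        art = articles.setdefault(aid, Article(article_id=aid, title=""))
        if part == "title":
            art.title_sentences.append(rec)
            art.title = (art.title + " " + rec.text).strip()
        elif part == "abstract":
            art.abstract_sentences.append(rec)
        else:
            art.body_sentences.append(rec)
    out = list(articles.values())
    for art in out:
        idx = [s.sentence_index for s in art.sentences]
        if len(set(idx)) != len(idx):
            raise CorpusParseError(
                f"article {art.article_id}: duplicate sentence_index"
            )
        art.title_sentences.sort(key=lambda s: s.sentence_index)
        art.abstract_sentences.sort(key=lambda s: s.sentence_index)
        art.body_sentences.sort(key=lambda s: s.sentence_index)
    return out


def read_corpus(path: str | Path, format: str | None = None) -> list[Article]:
    """Read a sentence-level corpus file (CSV or JSONL) into Articles."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".json"} else "csv"
    if format not in {"csv", "jsonl"}:
        raise ValueError(f"format must be csv or jsonl, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, dtype={"article_id": str, "labels": str,
                                      "section_path": str}, keep_default_na=False)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise CorpusParseError(f"missing required column: {missing[0]!r}")
        rows = df.to_dict("records")
    else:
        rows = []
        with path.open(encoding="utf-8") as fh:
            for ln in fh:
                ln = ln.strip()
                if ln:
                    rows.append(json.loads(ln))
    return _rows_to_articles(rows)


def write_corpus(articles: Sequence[Article], path: str | Path) -> None:
    """Write Articles back to the CSV schema (inverse of :func:`read_corpus`)."""
    rows = []
    for art in articles:
        for rec in art.sentences:
            rows.append(
                {
                    "article_id": rec.article_id,
                    "sentence_index": rec.sentence_index,
                    "part": rec.part,
                    "section_path": ">".join(rec.section_path),
                    "text": rec.text,
                    "labels": "|".join(sorted(rec.labels)),
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# --- JATS-style XML ---------------------------------------------------------

_SENT_BOUNDARY = re.compile(
    r"(?<=[.!?])\s+(?=[A-Z0-9(])"
)


def split_sentences(text: str) -> list[str]:
    """Default rule-based sentence splitter (period/question/exclamation
    followed by whitespace and an uppercase or numeric start)."""
    text = re.sub(r"\s+", " ", text).strip()
    if not text:
        return []
    return [s.strip() for s in _SENT_BOUNDARY.split(text) if s.strip()]


def read_jats_xml(
    path: str | Path,
    splitter: Callable[[str], list[str]] | None = None,
) -> Article:
    """Ingest a JATS-style XML full text into an Article.

    Section paths are built from nested ``<sec><title>`` elements,
    outermost first.  Sentence segmentation uses ``splitter`` (default:
    :func:`split_sentences`).
    """
    splitter = splitter or split_sentences
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed XML: {exc}") from exc
    root = tree.getroot()

    def text_of(el) -> str:
        return re.sub(r"\s+", " ", " ".join(el.itertext())).strip()

    title_el = root.find(".//article-title")
    title = text_of(title_el) if title_el is not None else ""
    aid_el = root.find(".//article-id")
    article_id = aid_el.text.strip() if aid_el is not None and aid_el.text else path.stem

    art = Article(article_id=article_id, title=title)
    counter = 0
    if title:
        art.title_sentences.append(
            SentenceRecord(article_id, counter, [], title, part="title")
        )
        counter += 1

    abstract_el = root.find(".//abstract")
    if abstract_el is not None:
        for sent in splitter(text_of(abstract_el)):
            art.abstract_sentences.append(
                SentenceRecord(article_id, counter, ["Abstract"], sent, part="abstract")
            )
            counter += 1

    body = root.find(".//body")
    if body is None:
        import warnings

        warnings.warn(f"{path}: XML has no <body>; body sentences empty")
        return art

    def walk(sec, path_so_far: list[str]) -> None:
        nonlocal counter
        t = sec.find("title")
        header = text_of(t) if t is not None else ""
        here = path_so_far + ([header] if header else [])
        for child in sec:
            if child.tag == "p":
                for sent in splitter(text_of(child)):
                    art.body_sentences.append(
                        SentenceRecord(article_id, counter, list(here), sent)
                    )
                    counter += 1
            elif child.tag == "sec":
                walk(child, here)

    for sec in body.findall("sec"):
        walk(sec, [])
    for p in body.findall("p"):
        for sent in splitter(text_of(p)):
            art.body_sentences.append(SentenceRecord(article_id, counter, [], sent))
            counter += 1
    return art


# --- statistics -------------------------------------------------------------

def corpus_stats(articles: Sequence[Article]) -> CorpusStats:
    """Descriptive counts over a corpus.

    ``mean_items_per_article`` averages the number of *distinct* item codes
    each article reports.
    """
    n_articles = len(articles)
    n_sentences = 0
    n_labeled = 0
    n_instances = 0
    per_article_items = []
    for art in articles:
        items: set[str] = set()
        for rec in art.sentences:
            n_sentences += 1
            if rec.labels:
                n_labeled += 1
                n_instances += len(rec.labels)
                items |= rec.labels
        per_article_items.append(len(items))
    mean_items = (
        sum(per_article_items) / n_articles if n_articles else 0.0
    )
    return CorpusStats(
        n_articles=n_articles,
        n_sentences=n_sentences,
        n_labeled_sentences=n_labeled,
        n_label_instances=n_instances,
        mean_items_per_article=mean_items,
    )


# --- predictions ------------------------------------------------------------

def write_predictions(predictions: Sequence, path: str | Path) -> None:
    """Serialize SentencePrediction objects as JSON-lines.

    The first line is a metadata header; probabilities are written at fixed
    precision (12 significant digits, re-read error < 1e-9).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"format": "consortcheck-predictions", "version": 1}) + "\n")
        for p in predictions:
            rec = {
                "article_id": p.article_id,
                "sentence_index": p.sentence_index,
                "label_set": list(p.label_set),
                "probabilities": [float(f"{v:.12g}") for v in p.probabilities],
                "predicted_labels": sorted(p.predicted_labels),
            }
            fh.write(json.dumps(rec) + "\n")


def read_predictions(path: str | Path) -> list["SentencePrediction"]:
    from .classifier import SentencePrediction
    import numpy as np

    path = Path(path)
    out = []
    with path.open(encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "consortcheck-predictions":
            raise CorpusParseError("not a predictions file")
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            d = json.loads(ln)
            out.append(
                SentencePrediction(
                    article_id=d["article_id"],
                    sentence_index=d["sentence_index"],
                    label_set=tuple(d["label_set"]),
                    probabilities=np.asarray(d["probabilities"], dtype=float),
                    predicted_labels=set(d["predicted_labels"]),
                )
            )
    return out
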