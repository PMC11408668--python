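"""Synthetic labeled RCT-like corpora and title/abstract fixtures.

The generator emulates the *statistical shape* of a sentence-annotated RCT
corpus — articles of one or two hundred sentences with nested IMRaD section
paths, multi-label sentence annotations over the 34 sentence-level checklist
items with strongly skewed label frequencies (the 8 rare items occur at
corpus counts well below 100), structured or unstructured abstracts and
randomized or neutral titles for the article-level rules — without imitating
real clinical prose.  Each item owns a reserved synthetic cue token
(``cue3a``, ``cue17b``, …) that labeled sentences contain with probability
``cue_strength``; this makes task difficulty controllable, from perfectly
separable (1.0) to pure noise (0.0).  A placement knob optionally puts the
cue in a *neighbor* sentence instead of the labeled sentence itself, so the
benefit of context windows is a testable property rather than an
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .corpus_io import Article, SentenceRecord
from .schema import ChecklistItem, load_checklist, sentence_level_items

_FILLER_VOCAB = (
    "the study cohort received scheduled assessments during follow up and "
    "outcomes were recorded by site staff according to protocol while data "
    "quality checks proceeded at each visit with standard procedures for "
    "documentation review monitoring adherence measurement analysis groups "
    "participants clinics baseline period weeks months visits records forms"
).split()

_SECTION_LAYOUT = [
    # (outermost header, nested subsections or None, share of body sentences)
    ("Introduction", None, 0.10),
    ("Methods", ("Patients", "Interventions", "Outcome measures", "Statistical analysis"), 0.35),
    ("Results", ("Participant flow", "Outcomes",), 0.30),
    ("Discussion", None, 0.15),
    ("Other information", None, 0.10),
]

_GROUP_FOR_HEADER = {
    "Introduction": "Introduction",
    "Methods": "Methods",
    "Results": "Results",
    "Discussion": "Discussion",
    "Other information": "OtherInformation",
}

_STRUCTURED_OPENERS = (
    "Background: the trial context is summarized here.",
    "OBJECTIVE. To assess the intervention in a randomized design.",
    "Methods: participants were allocated to two groups.",
)

_RANDOMIZED_TITLES = (
    "A Randomized Controlled Trial of Intervention X",
    "Cluster randomised evaluation of programme Y",
    "Effects of Z: a randomization-based study",
)

_NEUTRAL_TITLES = (
    "An observational cohort study of intervention X",
    "A prospective evaluation of programme Y",
    "Long-term outcomes of treatment Z in routine care",
)


def default_label_frequencies() -> dict[str, float]:
    """Per-sentence labeling probability for each sentence-level item,
    applied within the item's own section group.  Rare items are an order
    of magnitude scarcer than common ones, reproducing the skew that makes
    them hard to learn."""
    freqs: dict[str, float] = {}
    for it in sentence_level_items():
        if it.rare:
            freqs[it.code] = 0.01
        elif it.section_group == "Methods":
            freqs[it.code] = 0.04
        elif it.section_group == "Results":
            freqs[it.code] = 0.04
        elif it.section_group == "Discussion":
            freqs[it.code] = 0.06
        elif it.section_group == "Introduction":
            freqs[it.code] = 0.12
        else:  # OtherInformation
            freqs[it.code] = 0.12
    return freqs


def cue_token(code: str) -> str:
    """The reserved synthetic cue token for an item."""
    return f"cue{code}"


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic corpus."""

    n_articles: int = 30
    sentences_per_article: tuple[int, int] = (110, 200)
    label_frequencies: dict[str, float] = field(default_factory=default_label_frequencies)
    cue_strength: float = 1.0
    multi_label_rate: float = 0.15
    cue_placement: Literal["target", "neighbor"] = "target"
    structured_abstract_rate: float = 0.5
    randomized_title_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cue_strength <= 1:
            raise ValueError("cue_strength must be in [0, 1]")
        if not 0 <= self.multi_label_rate <= 1:
            raise ValueError("multi_label_rate must be in [0, 1]")
        for code, f in self.label_frequencies.items():
            if not 0 <= f <= 1:
                raise ValueError(f"frequency for {code} outside [0, 1]")
        if self.sentences_per_article[0] < 10:
            raise ValueError("articles must have at least 10 sentences")
        # Per-sentence expected label mass per section group; > 1 would force
        # more labels than the multi-label convention can represent sensibly.
        by_group: dict[str, float] = {}
        for it in sentence_level_items():
            f = self.label_frequencies.get(it.code, 0.0)
            by_group[it.section_group] = by_group.get(it.section_group, 0.0) + f
        for group, total in by_group.items():
            if total > 1.0:
                raise ValueError(
                    f"infeasible spec: label frequencies in {group} sum to "
                    f"{total:.2f} > 1"
                )


def _filler_sentence(rng: np.random.Generator, n_words: int) -> list[str]:
    idx = rng.integers(0, len(_FILLER_VOCAB), size=n_words)
    return [_FILLER_VOCAB[i] for i in idx]


def generate_corpus(spec: GeneratorSpec) -> list[Article]:
    """Generate a labeled synthetic corpus under ``spec`` (deterministic for
    a given seed)."""
    rng = np.random.default_rng(spec.seed)
    items_by_group: dict[str, list[ChecklistItem]] = {}
    for it in sentence_level_items():
        items_by_group.setdefault(it.section_group, []).append(it)

    articles: list[Article] = []
    for a in range(spec.n_articles):
        aid = f"synth{a:04d}"
        randomized = rng.random() < spec.randomized_title_rate
        structured = rng.random() < spec.structured_abstract_rate
        titles = _RANDOMIZED_TITLES if randomized else _NEUTRAL_TITLES
        title = titles[int(rng.integers(len(titles)))]

        art = Article(article_id=aid, title=title)
        counter = 0
        art.title_sentences.append(
            SentenceRecord(aid, counter, [], title, part="title")
        )
        counter += 1

        n_abstract = int(rng.integers(3, 7))
        for j in range(n_abstract):
            words = _filler_sentence(rng, int(rng.integers(8, 16)))
            text = " ".join(words).capitalize() + "."
            if j == 0 and structured:
                text = _STRUCTURED_OPENERS[int(rng.integers(len(_STRUCTURED_OPENERS)))]
            art.abstract_sentences.append(
                SentenceRecord(aid, counter, ["Abstract"], text, part="abstract")
            )
            counter += 1

        n_body = int(rng.integers(spec.sentences_per_article[0],
                                  spec.sentences_per_article[1] + 1))
        # deal body sentences to sections per layout shares
        pending: list[tuple[SentenceRecord, list[str]]] = []
        for header, subs, share in _SECTION_LAYOUT:
            n_here = max(2, int(round(share * n_body)))
            group = _GROUP_FOR_HEADER[header]
            group_items = items_by_group.get(group, [])
            for j in range(n_here):
                if subs:
                    sub = subs[min(len(subs) - 1, j * len(subs) // n_here)]
                    path = [header, sub]
                else:
                    path = [header]
                words = _filler_sentence(rng, int(rng.integers(8, 18)))
                labels: set[str] = set()
                for it in group_items:
                    f = spec.label_frequencies.get(it.code, 0.0)
                    if rng.random() < f:
                        labels.add(it.code)
                if len(labels) > 1 and rng.random() >= spec.multi_label_rate:
                    keep = sorted(labels)[int(rng.integers(len(labels)))]
                    labels = {keep}
                rec = SentenceRecord(
                    aid, counter, path, " ".join(words), labels=labels
                )
                pending.append((rec, words))
                counter += 1

        # cue insertion (optionally into a neighbor sentence)
        for k, (rec, words) in enumerate(pending):
            for code in sorted(rec.labels):
                if rng.random() >= spec.cue_strength:
                    continue
                if spec.cue_placement == "target":
                    host = k
                else:
                    host = k - 1 if k > 0 else k + 1
                host_rec, host_words = pending[host]
                pos = int(rng.integers(len(host_words) + 1))
                host_words.insert(pos, cue_token(code))
        for rec, words in pending:
            rec.text = " ".join(words)
            art.body_sentences.append(rec)
        articles.append(art)
    return articles


@dataclass(frozen=True)
class TitleAbstractFixture:
    article: Article
    gold_1a: bool
    gold_1b: bool


def generate_title_abstract_fixtures(
    n: int, seed: int = 0
) -> list[TitleAbstractFixture]:
    """Labeled fixtures for the 1a/1b rules, stratified over the four
    (randomized title, structured abstract) truth combinations and over stem
    and delimiter variants."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    stems_titles = [
        "A Randomized Controlled Trial of X",
        "Cluster randomised evaluation of Y",
        "RANDOMIZATION procedures in trial Z",
        "Effect of patient randomisation on outcomes",
        "  A randomized study with leading whitespace  ",
    ]
    neutral_titles = [
        "An observational cohort study",
        "A prospective evaluation of programme Y",
        "Case series of treatment Z",
        "A pragmatic crossover comparison of two regimens",
    ]
    structured_openers = [
        "Background: We conducted a trial.",
        "OBJECTIVE. To assess the intervention.",
        "Methods: participants were allocated at random.",
        "RESULTS: the intervention group improved.",
        "   Background: leading whitespace abstract.",
    ]
    plain_openers = [
        "We conducted a trial in twelve clinics.",
        "This report describes outcomes of a programme.",
        "Overall the intervention group improved.",
    ]
    out = []
    for i in range(n):
        gold_1a = bool((i // 2) % 2 == 0)
        gold_1b = bool(i % 2 == 0)
        title_pool = stems_titles if gold_1a else neutral_titles
        title = title_pool[int(rng.integers(len(title_pool)))]
        opener_pool = structured_openers if gold_1b else plain_openers
        opener = opener_pool[int(rng.integers(len(opener_pool)))]
        aid = f"ta{i:03d}"
        art = Article(article_id=aid, title=title)
        art.title_sentences.append(SentenceRecord(aid, 0, [], title, part="title"))
        art.abstract_sentences.append(
            SentenceRecord(aid, 1, ["Abstract"], opener, part="abstract")
        )
        art.abstract_sentences.append(
            SentenceRecord(
                aid, 2, ["Abstract"], "Further abstract text follows.", part="abstract"
            )
        )
        out.append(TitleAbstractFixture(article=art, gold_1a=gold_1a, gold_1b=gold_1b))
    return out
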