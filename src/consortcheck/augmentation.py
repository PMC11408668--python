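"""Training-data augmentation for rare checklist items.

Eight checklist items occur fewer than ~100 times in a realistic corpus and
are hard to learn.  Two families of augmentation are provided:

* **EDA** (easy data augmentation): random deletion, random insertion,
  random swap, and synonym replacement applied to single-label sentences of
  the rare items.  Synonyms come from a pluggable :class:`SynonymProvider`
  — a packaged general-English table by default, or any word→synonyms table
  (e.g. a clinical-terminology export) via :class:`TableSynonymProvider`.
  Six variations are generated per original sample.
* **LLM prompting**: deterministic prompt builders for (a) rephrasing an
  existing positively labeled sentence N times and (b) generating entirely
  new example sentences from an (edited) checklist-item description, plus a
  parser for the returned preceding/target/trailing triples and an
  accumulation loop that prompts repeatedly until a target instance count is
  reached.  Live API calls stay behind the minimal
  :class:`CompletionProvider` contract; tests and offline runs use canned
  providers.

Every augmentation instance carries exactly one label: only single-label
corpus sentences are eligible, and generated instances inherit either the
original sentence's label (rephrasing, EDA) or the label of the item
description used in the prompt (generative).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np

from .corpus_io import Article, SentenceRecord
from .schema import ChecklistItem, rare_items

logger = logging.getLogger(__name__)

EDA_OPS = ("synonym_replacement", "random_insertion", "random_swap", "random_deletion")
AUGMENTATION_METHODS = ("eda", "synonym_eda", "llm_rephrase", "llm_generative")

#: Sampling temperatures: creative for augmentation, deterministic for inference.
AUGMENTATION_TEMPERATURE = 1.0
INFERENCE_TEMPERATURE = 0.0

#: Default number of variations per original sample.
DEFAULT_N_AUG = 6

_STOPWORDS = frozenset(
    """a an the and or but if of in on at to for with by from as is are was were
    be been being this that these those it its we our they their he she his her
    not no nor so than then there here when where which who whom what why how
    all any both each few more most other some such only own same too very can
    will just do does did have has had having""".split()
)


@dataclass(frozen=True)
class AugmentationInstance:
    preceding: str
    target: str
    trailing: str
    labels: frozenset[str]
    method: str
    source_id: str
    section_path: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) != 1:
            raise ValueError("augmentation instances carry exactly one label")
        if not self.target:
            raise ValueError("target sentence must be non-empty")
        if self.method not in AUGMENTATION_METHODS:
            raise ValueError(f"unknown augmentation method: {self.method!r}")


# --------------------------------------------------------------------------
# Synonym providers
# --------------------------------------------------------------------------

class SynonymProvider(Protocol):
    def synonyms(self, word: str) -> list[str]: ...


class TableSynonymProvider:
    """Deterministic word→synonyms lookup backed by an in-memory table.

    Serves both UMLS-style clinical synonym exports (load the table from a
    TSV) and test fixtures.  A word is never returned as its own synonym.
    """

    def __init__(self, table: dict[str, Sequence[str]]):
        self._table = {
            w.lower(): [s for s in syns if s.lower() != w.lower()]
            for w, syns in table.items()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableSynonymProvider":
        table: dict[str, list[str]] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            word, _, syns = ln.partition("\t")
            table[word] = [s for s in syns.split("|") if s]
        return cls(table)

    def synonyms(self, word: str) -> list[str]:
        return list(self._table.get(word.lower(), []))


def general_synonym_provider() -> TableSynonymProvider:
    """The packaged general-English synonym table."""
    text = (
        resources.files("consortcheck.data")
        .joinpath("general_synonyms.tsv")
        .read_text(encoding="utf-8")
    )
    table: dict[str, list[str]] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        word, _, syns = ln.partition("\t")
        table[word] = [s for s in syns.split("|") if s]
    return TableSynonymProvider(table)


# --------------------------------------------------------------------------
# Candidate selection
# --------------------------------------------------------------------------

def label_counts(articles: Sequence[Article]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for art in articles:
        for rec in art.sentences:
            for code in rec.labels:
                counts[code] = counts.get(code, 0) + 1
    return counts


def select_candidates(
    articles: Sequence[Article],
    counts: dict[str, int] | None = None,
    rare: set[str] | None = None,
) -> list[SentenceRecord]:
    """Sentences eligible for augmentation: exactly one label, and that
    label one of the rare items."""
    rare = rare if rare is not None else rare_items()
    out = []
    for art in articles:
        for rec in art.sentences:
            if len(rec.labels) == 1 and next(iter(rec.labels)) in rare:
                out.append(rec)
    return out


# --------------------------------------------------------------------------
# EDA transforms
# --------------------------------------------------------------------------

def _n_ops(rate: float, length: int) -> int:
    return math.ceil(rate * length) if rate > 0 else 0


def eda_transform(
    sentence: str,
    op_kind: str,
    rate: float,
    rng: np.random.Generator,
    synonyms: SynonymProvider,
) -> str:
    """Apply one EDA operation to a sentence.

    deletion: each word dropped independently with probability ``rate`` (at
    least one word always survives); swap: ⌈rate·L⌉ random position pairs
    exchanged; insertion: synonyms of ⌈rate·L⌉ random words inserted at
    random positions; synonym_replacement: ⌈rate·L⌉ eligible (non-stopword)
    words replaced by a random synonym.  Deterministic for a given ``rng``
    state.
    """
    if op_kind not in EDA_OPS:
        raise ValueError(f"unknown EDA operation: {op_kind!r}")
    if not 0 <= rate <= 1:
        raise ValueError("rate must be within [0, 1]")
    words = sentence.split()
    if not words:
        return sentence
    if rate == 0:
        return sentence

    if op_kind == "random_deletion":
        keep = [w for w in words if rng.random() >= rate]
        if not keep:
            keep = [words[int(rng.integers(len(words)))]]
        return " ".join(keep)

    n = _n_ops(rate, len(words))
    if op_kind == "random_swap":
        out = list(words)
        for _ in range(n):
            if len(out) < 2:
                break
            i, j = rng.choice(len(out), size=2, replace=False)
            out[i], out[j] = out[j], out[i]
        return " ".join(out)

    if op_kind == "random_insertion":
        out = list(words)
        for _ in range(n):
            candidates = [w for w in out if synonyms.synonyms(w)]
            if not candidates:
                break
            word = candidates[int(rng.integers(len(candidates)))]
            syns = synonyms.synonyms(word)
            syn = syns[int(rng.integers(len(syns)))]
            pos = int(rng.integers(len(out) + 1))
            out.insert(pos, syn)
        return " ".join(out)

    # synonym_replacement
    out = list(words)
    eligible = [
        i
        for i, w in enumerate(out)
        if w.lower() not in _STOPWORDS and synonyms.synonyms(w)
    ]
    rng.shuffle(eligible)
    for i in eligible[:n]:
        syns = synonyms.synonyms(out[i])
        out[i] = syns[int(rng.integers(len(syns)))]
    return " ".join(out)


def eda_augment(
    record: SentenceRecord,
    rng: np.random.Generator,
    synonyms: SynonymProvider | None = None,
    n_aug: int = DEFAULT_N_AUG,
    alpha: float = 0.1,
    preceding: str = "",
    trailing: str = "",
    method: str = "eda",
) -> list[AugmentationInstance]:
    """Generate ``n_aug`` perturbed variations of a single-label sentence.

    Each variation applies one randomly chosen EDA operation at rate
    ``alpha`` (default 0.1, the operation family's conventional setting).
    Context sentences and the section path are copied from the original.
    """
    if len(record.labels) != 1:
        raise ValueError("EDA augmentation requires a single-label sentence")
    synonyms = synonyms if synonyms is not None else general_synonym_provider()
    out = []
    for _ in range(n_aug):
        op = EDA_OPS[int(rng.integers(len(EDA_OPS)))]
        variant = eda_transform(record.text, op, alpha, rng, synonyms)
        out.append(
            AugmentationInstance(
                preceding=preceding,
                target=variant if variant else record.text,
                trailing=trailing,
                labels=frozenset(record.labels),
                method=method,
                source_id=f"{record.article_id}:{record.sentence_index}",
                section_path=tuple(record.section_path),
            )
        )
    return out


# --------------------------------------------------------------------------
# LLM prompt construction
# --------------------------------------------------------------------------

ROLE_PREAMBLE = (
    "You are a scientific researcher writing a research paper for "
    "randomized clinical trials."
)

REPHRASE_TEMPLATE = (
    ROLE_PREAMBLE
    + " Please rephrase the following sentence {n} times: {sentence}. "
    "For the {n} rephrased sentences, also provide an example preceding "
    "sentence and an example trailing sentence. Vary the sentence structure "
    "and sentence complexity for each sentence. Also, vary the use of "
    "introductory prepositional phrases in all sentences"
)

GENERATIVE_TEMPLATE = (
    ROLE_PREAMBLE
    + " From your research paper, please provide {n} different 1 sentence "
    "examples of the following: {description}. For each example, also "
    "provide an example preceding sentence and an example trailing "
    "sentence. Vary the sentence structure and sentence complexity for "
    "each example. Also, vary the use of introductory prepositional "
    "phrases in all examples"
)


def build_rephrase_prompt(sentence: str, n: int = DEFAULT_N_AUG) -> str:
    """Rephrasing prompt (N defaults to 6 variations)."""
    if not sentence or not sentence.strip():
        raise ValueError("sentence must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    return REPHRASE_TEMPLATE.format(n=n, sentence=sentence.strip().rstrip("."))


def build_generative_prompt(item: ChecklistItem, n: int) -> str:
    """Generative prompt built from the item's edited description."""
    description = edit_item_description(item.description)
    return GENERATIVE_TEMPLATE.format(n=n, description=description)


def edit_item_description(description: str) -> str:
    """Edit a checklist-item description for generation quality.

    In order: "with reasons" becomes "with specifics"; the hedges
    "when applicable" and "if relevant" are removed; illustrative
    "such as …" spans (to the next comma or closing parenthesis) are
    removed; spacing, empty parentheses and dangling commas are normalized.
    """
    text = description
    text = re.sub(r"with reasons", "with specifics", text, flags=re.I)
    text = re.sub(r"\s*,?\s*\b(when applicable|if relevant)\b\s*,?\s*", ", ", text, flags=re.I)
    text = re.sub(r"\bsuch as [^,)]*", "", text)
    text = re.sub(r"\(\s*\)", "", text)
    text = re.sub(r"\s+,", ",", text)
    text = re.sub(r",\s*,", ",", text)
    text = re.sub(r"\s{2,}", " ", text)
    text = text.strip().strip(",").strip()
    return text


# --------------------------------------------------------------------------
# Response parsing and accumulation
# --------------------------------------------------------------------------

class CompletionProvider(Protocol):
    """Minimal contract for a text-completion backend."""

    def complete(self, prompt: str, temperature: float = AUGMENTATION_TEMPERATURE) -> str: ...


_FIELD_PATTERNS = {
    "preceding": re.compile(r"^\s*(?:\d+[.)]\s*)?preceding(?:\s+sentence)?\s*[:\-]\s*(.*)$", re.I),
    "target": re.compile(
        r"^\s*(?:\d+[.)]\s*)?(?:sentence|target|rephrased(?:\s+sentence)?|example(?:\s+sentence)?)\s*[:\-]\s*(.*)$",
        re.I,
    ),
    "trailing": re.compile(r"^\s*(?:\d+[.)]\s*)?(?:trailing|following)(?:\s+sentence)?\s*[:\-]\s*(.*)$", re.I),
}

_CANONICAL_HEADER = {
    "Introduction": ("Introduction",),
    "Methods": ("Methods",),
    "Results": ("Results",),
    "Discussion": ("Discussion",),
    "OtherInformation": (),
    "TitleAbstract": (),
}


def parse_augmentation_response(
    text: str,
    label: str,
    method: str,
    source_id: str = "llm",
    section_group: str | None = None,
) -> list[AugmentationInstance]:
    """Extract (preceding, target, trailing) triples from a completion.

    Lines labeled ``Preceding:``/``Sentence:``/``Trailing:`` (several common
    spellings accepted) are grouped into blocks; blocks missing a target
    sentence are skipped with a logged warning.
    """
    section_path = _CANONICAL_HEADER.get(section_group or "", ())
    blocks: list[dict[str, str]] = []
    current: dict[str, str] = {}
    for line in text.splitlines():
        matched = None
        for key, pat in _FIELD_PATTERNS.items():
            m = pat.match(line)
            if m:
                matched = (key, m.group(1).strip())
                break
        if matched is None:
            continue
        key, value = matched
        if key in current:
            blocks.append(current)
            current = {}
        current[key] = value
    if current:
        blocks.append(current)

    out = []
    for blk in blocks:
        target = blk.get("target", "")
        if not target:
            logger.warning("skipping malformed augmentation block: %r", blk)
            continue
        out.append(
            AugmentationInstance(
                preceding=blk.get("preceding", ""),
                target=target,
                trailing=blk.get("trailing", ""),
                labels=frozenset({label}),
                method=method,
                source_id=source_id,
                section_path=section_path,
            )
        )
    if not out:
        logger.warning("no parsable augmentation triples in response")
    return out


def accumulate_generative(
    provider: CompletionProvider,
    item: ChecklistItem,
    batch_n: int = 8,
    target_total: int = 100,
    max_iterations: int = 50,
) -> list[AugmentationInstance]:
    """Prompt repeatedly until ``target_total`` generative instances are
    collected (or the iteration cap is hit, with a warning)."""
    collected: list[AugmentationInstance] = []
    prompt = build_generative_prompt(item, batch_n)
    for _ in range(max_iterations):
        if len(collected) >= target_total:
            break
        response = provider.complete(prompt, temperature=AUGMENTATION_TEMPERATURE)
        collected.extend(
            parse_augmentation_response(
                response,
                label=item.code,
                method="llm_generative",
                source_id=f"generative:{item.code}",
                section_group=item.section_group,
            )
        )
    if len(collected) < target_total:
        logger.warning(
            "iteration cap reached with %d/%d instances for item %s",
            len(collected),
            target_total,
            item.code,
        )
    return collected


# --------------------------------------------------------------------------
# Bridging to the classifier
# --------------------------------------------------------------------------

def to_training_instance(inst: AugmentationInstance, config) -> "TrainingInstance":
    """Assemble an augmentation instance into a classifier training
    instance under the model's representation settings."""
    from .classifier import TrainingInstance, _label_vector
    from .representation import ContextWindow, assemble_input, truncate_segments
    from .representation import EncoderInput

    window = ContextWindow(
        preceding=inst.preceding,
        target=inst.target,
        trailing=inst.trailing,
        preceding_path=inst.section_path,
        target_path=inst.section_path,
        trailing_path=inst.section_path,
    )
    enc = assemble_input(
        window,
        header_mode=config.header_mode,
        position_kind="none",
        context=config.context,
    )
    enc = EncoderInput(
        segments=truncate_segments(enc.segments, config.max_tokens),
        position=enc.position,
    )
    return TrainingInstance(
        article_id=f"aug:{inst.source_id}",
        sentence_index=-1,
        inp=enc,
        label_vector=_label_vector(set(inst.labels), config.label_set),
    )
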