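"""CONSORT 2010 fine-grained item taxonomy.

The CONSORT 2010 checklist decomposes 25 reporting requirements for
randomized controlled trial (RCT) publications into 37 fine-grained items
(multi-part items carry letter suffixes, e.g. 3a/3b).  This module ships the
item table as a packaged, user-overridable resource and exposes the label-set
selections the screening pipeline relies on:

* 1a (randomized in title) and 1b (structured abstract) are *article-level*
  items, handled by rules rather than the sentence classifier;
* 2a (Background) is excluded from sentence classification — virtually every
  article reports it, so screening it carries no information;
* the remaining 34 items are sentence-level labels;
* 8 items occur fewer than ~100 times in a realistic corpus and are the
  targets of data augmentation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

SECTION_GROUPS = (
    "TitleAbstract",
    "Introduction",
    "Methods",
    "Results",
    "Discussion",
    "OtherInformation",
)

#: Item codes augmentation targets (fewer than 100 corpus instances).
RARE_ITEM_CODES = frozenset({"3b", "6b", "7b", "9", "11b", "12b", "14b", "21"})


class ChecklistResourceError(RuntimeError):
    """Raised when the packaged checklist resource is missing or corrupt."""


@dataclass(frozen=True)
class ChecklistItem:
    """One fine-grained CONSORT 2010 checklist item."""

    code: str
    title: str
    description: str
    section_group: str
    article_level: bool
    sentence_level: bool
    rare: bool

    def __post_init__(self) -> None:
        if self.section_group not in SECTION_GROUPS:
            raise ValueError(f"unknown section group: {self.section_group!r}")


def normalize_code(code: str) -> str:
    """Normalize an item code to lowercase alphanumeric form (``3A`` → ``3a``)."""
    norm = re.sub(r"[^0-9a-z]", "", code.strip().lower())
    if not norm:
        raise ValueError(f"empty item code: {code!r}")
    return norm


def _code_sort_key(code: str) -> tuple[int, str]:
    m = re.match(r"(\d+)([a-z]*)$", code)
    if m is None:
        raise ValueError(f"malformed item code: {code!r}")
    return int(m.group(1)), m.group(2)


def load_checklist(path: str | Path | None = None) -> list[ChecklistItem]:
    """Load the 37-item checklist, ordered by code.

    Parameters
    ----------
    path:
        Optional override for the packaged tab-separated item table
        (columns: code, title, description, section_group, article_level,
        sentence_level, rare).
    """
    if path is None:
        try:
            text = (
                resources.files("consortcheck.data")
                .joinpath("checklist_items.tsv")
                .read_text(encoding="utf-8")
            )
        except (FileNotFoundError, ModuleNotFoundError) as exc:
            raise ChecklistResourceError(
                "packaged checklist resource is missing"
            ) from exc
    else:
        p = Path(path)
        if not p.exists():
            raise ChecklistResourceError(f"checklist table not found: {p}")
        text = p.read_text(encoding="utf-8")

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ChecklistResourceError("checklist table is empty")
    header = lines[0].split("\t")
    expected = [
        "code",
        "title",
        "description",
        "section_group",
        "article_level",
        "sentence_level",
        "rare",
    ]
    if header != expected:
        raise ChecklistResourceError(
            f"checklist table header mismatch: {header!r}"
        )

    items: list[ChecklistItem] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(expected):
            raise ChecklistResourceError(f"malformed checklist row: {ln!r}")
        code = normalize_code(fields[0])
        if code in seen:
            raise ChecklistResourceError(f"duplicate item code: {code}")
        seen.add(code)
        items.append(
            ChecklistItem(
                code=code,
                title=fields[1],
                description=fields[2],
                section_group=fields[3],
                article_level=fields[4] == "1",
                sentence_level=fields[5] == "1",
                rare=fields[6] == "1",
            )
        )
    items.sort(key=lambda it: _code_sort_key(it.code))
    if len(items) != 37:
        raise ChecklistResourceError(
            f"expected 37 checklist items, found {len(items)}"
        )
    return items


def sentence_level_items(
    checklist: list[ChecklistItem] | None = None,
) -> list[ChecklistItem]:
    """The 34 items classified at the sentence level (excludes 1a, 1b, 2a)."""
    checklist = checklist if checklist is not None else load_checklist()
    return [it for it in checklist if it.sentence_level]


def rare_items(checklist: list[ChecklistItem] | None = None) -> set[str]:
    """Codes of the 8 augmentation-eligible rare items."""
    checklist = checklist if checklist is not None else load_checklist()
    return {it.code for it in checklist if it.rare}


def items_for_section_group(
    group: str, checklist: list[ChecklistItem] | None = None
) -> list[ChecklistItem]:
    """Sentence-level items expected in a given manuscript section group."""
    if group not in SECTION_GROUPS:
        raise ValueError(
            f"unknown section group {group!r}; expected one of {SECTION_GROUPS}"
        )
    return [
        it
        for it in sentence_level_items(checklist)
        if it.section_group == group
    ]


def item_by_code(
    code: str, checklist: list[ChecklistItem] | None = None
) -> ChecklistItem:
    code = normalize_code(code)
    checklist = checklist if checklist is not None else load_checklist()
    for it in checklist:
        if it.code == code:
            return it
    raise KeyError(f"unknown checklist item code: {code}")
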