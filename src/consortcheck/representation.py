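"""Classifier input assembly: header-prefixed context windows and sentence
position features.

Many checklist items are reported over several contiguous sentences, so the
classifier may consume the target sentence together with its immediate
neighbors (±1 sentence, never crossing article boundaries).  Each sentence is
prepended with its nested section headers (e.g. ``Methods Patients <text>``),
and an optional sentence-position feature — the absolute index or the
relative position discretized into 10 equal bins — is attached for the
classification head to embed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .corpus_io import Article, SentenceRecord

HeaderMode = Literal["none", "innermost", "outermost", "all"]
PositionKind = Literal["none", "absolute", "relative"]

HEADER_MODES = ("none", "innermost", "outermost", "all")
POSITION_KINDS = ("none", "absolute", "relative")

#: Cap on the absolute-position embedding vocabulary; longer articles clip.
ABSOLUTE_POSITION_CAP = 512
N_RELATIVE_BINS = 10


@dataclass(frozen=True)
class ContextWindow:
    preceding: str
    target: str
    trailing: str
    preceding_path: tuple[str, ...] = ()
    target_path: tuple[str, ...] = ()
    trailing_path: tuple[str, ...] = ()


@dataclass(frozen=True)
class PositionFeature:
    kind: str
    value: int

    def __post_init__(self) -> None:
        if self.kind not in POSITION_KINDS:
            raise ValueError(f"unknown position kind: {self.kind!r}")
        if self.kind == "relative" and not 0 <= self.value < N_RELATIVE_BINS:
            raise ValueError(f"relative bin out of range: {self.value}")
        if self.value < 0:
            raise ValueError("position value must be non-negative")


@dataclass(frozen=True)
class EncoderInput:
    """Segments ready for the encoder: 1 (no-context) or 3 (context mode),
    each already header-prefixed.  The encoder adapter joins segments with
    its separator token and prepends its classification marker."""

    segments: tuple[str, ...]
    position: PositionFeature | None = None

    def __post_init__(self) -> None:
        if len(self.segments) not in (1, 3):
            raise ValueError("EncoderInput must have 1 or 3 segments")


def _prefix(path: tuple[str, ...] | list[str], text: str, mode: HeaderMode) -> str:
    if mode not in HEADER_MODES:
        raise ValueError(f"unknown header mode: {mode!r}")
    path = list(path)
    if mode == "none" or not path:
        return text
    if mode == "innermost":
        headers = [path[-1]]
    elif mode == "outermost":
        headers = [path[0]]
    else:
        headers = path
    prefix = " ".join(headers)
    return f"{prefix} {text}" if text else prefix


def prefix_with_headers(record: SentenceRecord, mode: HeaderMode) -> str:
    """Prepend (nested) section headers to a sentence per ``mode``."""
    return _prefix(record.section_path, record.text, mode)


def build_context_window(article: Article, i: int) -> ContextWindow:
    """Window of sentence ``i`` with its in-article neighbors (empty strings
    at article boundaries)."""
    sentences = article.sentences
    if not 0 <= i < len(sentences):
        raise IndexError(
            f"sentence index {i} out of range for article "
            f"{article.article_id} with {len(sentences)} sentences"
        )
    prev_rec = sentences[i - 1] if i > 0 else None
    next_rec = sentences[i + 1] if i + 1 < len(sentences) else None
    return ContextWindow(
        preceding=prev_rec.text if prev_rec else "",
        target=sentences[i].text,
        trailing=next_rec.text if next_rec else "",
        preceding_path=tuple(prev_rec.section_path) if prev_rec else (),
        target_path=tuple(sentences[i].section_path),
        trailing_path=tuple(next_rec.section_path) if next_rec else (),
    )


def assemble_input(
    window: ContextWindow,
    header_mode: HeaderMode = "all",
    position_kind: PositionKind = "none",
    *,
    context: bool = True,
    index: int | None = None,
    n_sentences: int | None = None,
) -> EncoderInput:
    """Assemble the encoder input from a context window.

    Empty neighbor segments stay in place as empty strings so the 3-segment
    layout is stable at article boundaries.
    """
    if context:
        segments = (
            _prefix(window.preceding_path, window.preceding, header_mode)
            if window.preceding
            else "",
            _prefix(window.target_path, window.target, header_mode),
            _prefix(window.trailing_path, window.trailing, header_mode)
            if window.trailing
            else "",
        )
    else:
        segments = (_prefix(window.target_path, window.target, header_mode),)

    position: PositionFeature | None = None
    if position_kind != "none":
        if index is None:
            raise ValueError("position features require the sentence index")
        if position_kind == "absolute":
            position = absolute_position_feature(index)
        elif position_kind == "relative":
            if n_sentences is None:
                raise ValueError("relative position requires n_sentences")
            position = PositionFeature(
                "relative", relative_position_bin(index, n_sentences)
            )
        else:
            raise ValueError(f"unknown position kind: {position_kind!r}")
    return EncoderInput(segments=segments, position=position)


def relative_position_bin(index: int, n_sentences: int) -> int:
    """Discretize relative article position into 10 half-open bins
    (0–0.1, 0.1–0.2, …; the last bin is closed so the final sentence maps
    to bin 9).  Relative position is ``index / (n_sentences - 1)`` so the
    top bin is always populated; single-sentence articles map to bin 0."""
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    if not 0 <= index < n_sentences:
        raise ValueError(f"index {index} out of range for {n_sentences} sentences")
    if n_sentences == 1:
        return 0
    rel = index / (n_sentences - 1)
    return min(int(rel / 0.1), N_RELATIVE_BINS - 1)


def absolute_position_feature(index: int, cap: int = ABSOLUTE_POSITION_CAP) -> PositionFeature:
    """Absolute sentence index, clipped to the embedding vocabulary cap."""
    if index < 0:
        raise ValueError("index must be non-negative")
    return PositionFeature("absolute", min(index, cap))


def truncate_segments(
    segments: tuple[str, ...], max_tokens: int
) -> tuple[str, ...]:
    """Trim whitespace tokens to fit ``max_tokens`` across all segments,
    dropping from the right of the preceding segment first, then the
    trailing, then the target — the target sentence carries the label and is
    preserved longest."""
    toks = [seg.split() for seg in segments]
    if len(toks) == 1:
        order = [0]
    else:
        order = [0, 2, 1]
    total = sum(len(t) for t in toks)
    for idx in order:
        if total <= max_tokens:
            break
        drop = min(len(toks[idx]), total - max_tokens)
        if drop:
            toks[idx] = toks[idx][: len(toks[idx]) - drop]
            total -= drop
    return tuple(" ".join(t) for t in toks)
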