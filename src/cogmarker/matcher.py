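"""Message-level CDS matching: presence indicators per distortion category.

A message is scored 1 for a pattern set if at least one of its patterns
matches the normalized message text; hit multiplicity is irrelevant to the
indicator but matched pattern ids are retained for diagnostics.  Matching is
strictly per message — patterns never span adjacent messages — and ignores
topic and context by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import re

from .corpus import Corpus, Role
from .lexicon import CdsLexicon, CdsPattern, DistortionType, MatchOptions, compile_pattern, normalize_text

__all__ = ["MatchAnnotation", "CdsMatcher", "match_message", "annotate_corpus", "annotations_to_frame"]


@dataclass(frozen=True)
class MatchAnnotation:
    """Per-message match result."""

    session_id: str
    msg_index: int
    role: Role
    flags: dict[str, int]  # category code -> 0/1
    any_cds: int
    matched_pattern_ids: tuple[int, ...] = field(default_factory=tuple)


class CdsMatcher:
    """Compiled matcher over a lexicon.

    Per category a single alternation regex is used as a fast screen; only
    on a screen hit is the per-pattern pass run to recover matched ids.
    """

    def __init__(self, lexicon: CdsLexicon, options: MatchOptions | None = None) -> None:
        self.lexicon = lexicon
        self.options = options or MatchOptions()
        self._compiled: dict[int, re.Pattern] = {
            p.id: compile_pattern(p, self.options) for p in lexicon.patterns
        }
        self._category_screen: dict[DistortionType, re.Pattern] = {}
        flags = re.IGNORECASE if self.options.case_insensitive else 0
        for category, patterns in lexicon.by_category.items():
            if not patterns:
                continue
            alternation = "|".join(self._compiled[p.id].pattern for p in patterns)
            self._category_screen[category] = re.compile(alternation, flags)

    def match_message(
        self, text: str, patterns: Sequence[CdsPattern] | None = None
    ) -> tuple[int, list[int]]:
        """Indicator and matched ids for one message against a pattern set
        (default: the whole lexicon). Ids are returned in pattern-id order."""
        norm = normalize_text(text)
        if not norm:
            return 0, []
        if patterns is None:
            patterns = self.lexicon.patterns
        ids = sorted(
            p.id for p in patterns if self._compiled[p.id].search(norm) is not None
        )
        return (1 if ids else 0), ids

    def _annotate_text(self, text: str) -> tuple[dict[str, int], list[int]]:
        norm = normalize_text(text)
        flags = {c.code: 0 for c in DistortionType}
        ids: list[int] = []
        if not norm:
            return flags, ids
        for category, screen in self._category_screen.items():
            if screen.search(norm) is None:
                continue
            hits = [
                p.id
                for p in self.lexicon.by_category[category]
                if self._compiled[p.id].search(norm) is not None
            ]
            if hits:
                flags[category.code] = 1
                ids.extend(hits)
        return flags, sorted(ids)

    def annotate_corpus(self, corpus: Corpus) -> list[MatchAnnotation]:
        """One annotation per non-system message, in corpus order."""
        annotations = []
        for session in corpus.sessions:
            for idx, message in enumerate(session.messages):
                if message.role is Role.SYSTEM:
                    continue
                flags, ids = self._annotate_text(message.text)
                annotations.append(
                    MatchAnnotation(
                        session_id=session.session_id,
                        msg_index=idx,
                        role=message.role,
                        flags=flags,
                        any_cds=1 if ids else 0,
                        matched_pattern_ids=tuple(ids),
                    )
                )
        return annotations


def match_message(
    lexicon: CdsLexicon,
    patterns: Sequence[CdsPattern] | None,
    text: str,
    options: MatchOptions | None = None,
) -> tuple[int, list[int]]:
    """Functional form of :meth:`CdsMatcher.match_message` (builds a matcher
    per call; prefer the class for bulk work)."""
    return CdsMatcher(lexicon, options).match_message(text, patterns)


def annotate_corpus(
    lexicon: CdsLexicon, corpus: Corpus, options: MatchOptions | None = None
) -> list[MatchAnnotation]:
    return CdsMatcher(lexicon, options).annotate_corpus(corpus)


def annotations_to_frame(annotations: Iterable[MatchAnnotation]) -> pd.DataFrame:
    """Tabular form: one row per annotated message, one column per category
    code, plus ``any_cds`` and semicolon-joined ``matched_pattern_ids``."""
    codes = [c.code for c in DistortionType]
    rows = []
    for a in annotations:
        row = {"session_id": a.session_id, "msg_index": a.msg_index, "role": a.role.value}
        row.update({code: a.flags.get(code, 0) for code in codes})
        row["any_cds"] = a.any_cds
        row["matched_pattern_ids"] = ";".join(str(i) for i in a.matched_pattern_ids)
        rows.append(row)
    columns = ["session_id", "msg_index", "role", *codes, "any_cds", "matched_pattern_ids"]
    return pd.DataFrame(rows, columns=columns)
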