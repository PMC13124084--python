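"""Dutch cognitive-distortion schemata (CDS) lexicon.

The lexicon is shipped as a verbatim UTF-8 text resource with one category
per line (``<category name>\\t<patterns>``), patterns separated by a comma
followed by a space.  Pattern text is written in a small regex dialect:
alternations ``(a|b)``, optional elements ``x?`` / ``(xy)?``, character
classes ``[ab]``, and a gap construct ``(.+ |)`` standing for optional
intervening words between two anchored phrases.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

from .errors import LexiconError

__all__ = [
    "DistortionType",
    "CdsPattern",
    "CdsLexicon",
    "MatchOptions",
    "load_builtin_lexicon",
    "parse_lexicon_text",
    "compile_pattern",
    "category_counts",
]

_RESOURCE = "cds_lexicon_nl.tsv"


class DistortionType(enum.Enum):
    """The 12 conventional cognitive-distortion categories.

    Enum order is the canonical category (row) order of the lexicon.
    """

    CATASTROPHIZING = ("Catastrophizing", "c")
    DICHOTOMOUS_REASONING = ("Dichotomous reasoning", "dr")
    DISQUALIFYING_POSITIVE = ("Disqualifying the positive", "dtp")
    EMOTIONAL_REASONING = ("Emotional reasoning", "er")
    FORTUNE_TELLING = ("Fortune-telling", "f")
    LABELING = ("Labeling and mislabeling", "lam")
    MAGNIFICATION_MINIMIZATION = ("Magnification and minimization", "mam")
    MENTAL_FILTERING = ("Mental filtering", "mf")
    MINDREADING = ("Mindreading", "m")
    OVERGENERALIZING = ("Overgeneralizing", "o")
    PERSONALIZING = ("Personalizing", "p")
    SHOULD_STATEMENTS = ("Should statements", "ss")

    def __init__(self, label: str, code: str) -> None:
        self.label = label
        self.code = code

    @classmethod
    def from_label(cls, label: str) -> "DistortionType":
        for member in cls:
            if member.label.lower() == label.strip().lower():
                return member
        raise LexiconError(f"unknown distortion category label: {label!r}")

    @classmethod
    def from_code(cls, code: str) -> "DistortionType":
        for member in cls:
            if member.code == code:
                return member
        raise LexiconError(f"unknown distortion category code: {code!r}")


#: characters that are typesetting artifacts in the printed table, never
#: part of a pattern's language
_QUOTE_CHARS = "\"“”„"

#: regex metacharacters whose presence marks a pattern as non-literal
_META = set("(|)?[].+*")

# the printed gap construct, optionally absorbing one following space so the
# two printed variants "(.+ |) niet" and "(.+ |)niet" compile identically
_GAP = re.compile(r"\(\.\+ \|\) ?")


def _normalize_pattern(raw: str) -> str:
    text = unicodedata.normalize("NFC", raw)
    text = "".join(ch for ch in text if ch not in _QUOTE_CHARS)
    text = re.sub(r"\s+", " ", text).strip()
    return text


def normalize_text(text: str) -> str:
    """Normalize message text prior to matching: NFC, casefold to lower
    case, collapse whitespace runs to single spaces."""
    text = unicodedata.normalize("NFC", text)
    text = re.sub(r"\s+", " ", text).strip()
    return text.lower()


@dataclass(frozen=True)
class MatchOptions:
    """Options governing pattern compilation.

    gap_cap:
        Maximum number of characters a gap construct may span, or ``None``
        for unlimited (within one message).  Exposed for sensitivity
        analysis only.
    case_insensitive:
        Case-insensitive matching (the default; the lexicon is lower case).
    """

    gap_cap: int | None = None
    case_insensitive: bool = True


@dataclass(frozen=True)
class CdsPattern:
    """One schema of the lexicon.

    ``raw`` is byte-for-byte the printed pattern text; ``normalized`` has
    typographic quote artifacts removed and whitespace runs collapsed.
    """

    id: int
    category: DistortionType
    raw: str
    normalized: str

    @property
    def is_regex(self) -> bool:
        return any(ch in _META for ch in self.normalized)


def compile_pattern(pattern: CdsPattern, options: MatchOptions | None = None) -> re.Pattern:
    """Compile a lexicon pattern into a Python regex.

    The compiled matcher performs substring search over normalized text with
    word-boundary anchoring at both edges (zero-width lookarounds, so edges
    that are themselves non-word characters — apostrophes, optional suffixes
    — still anchor correctly).  The gap construct becomes ``(?: .+)? ``:
    either a single space or arbitrary intervening material bounded by
    spaces; ``.`` never crosses a newline, and hence never a message
    boundary.
    """
    options = options or MatchOptions()
    if not pattern.normalized:
        raise LexiconError(f"pattern {pattern.id} is empty after normalization")
    if options.gap_cap is not None:
        gap = f"(?: .{{1,{int(options.gap_cap)}}})? "
    else:
        gap = "(?: .+)? "
    source = _GAP.sub(gap, pattern.normalized)
    wrapped = rf"(?<!\w)(?:{source})(?!\w)"
    flags = re.IGNORECASE if options.case_insensitive else 0
    try:
        return re.compile(wrapped, flags)
    except re.error as exc:
        raise LexiconError(f"pattern {pattern.id} ({pattern.raw!r}) does not compile: {exc}") from exc


@dataclass
class CdsLexicon:
    """Ordered collection of CDS patterns grouped into the 12 categories."""

    patterns: list[CdsPattern] = field(default_factory=list)

    @property
    def by_category(self) -> dict[DistortionType, list[CdsPattern]]:
        out: dict[DistortionType, list[CdsPattern]] = {c: [] for c in DistortionType}
        for p in self.patterns:
            out[p.category].append(p)
        return out

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterable[CdsPattern]:
        return iter(self.patterns)

    def category(self, which: DistortionType | str) -> list[CdsPattern]:
        """Patterns of one category, accepted as enum member, code, or label."""
        if isinstance(which, str):
            try:
                which = DistortionType.from_code(which)
            except LexiconError:
                which = DistortionType.from_label(which)
        return [p for p in self.patterns if p.category is which]

    def to_frame(self) -> pd.DataFrame:
        """Tabular export with one row per pattern."""
        return pd.DataFrame(
            {
                "id": [p.id for p in self.patterns],
                "category_code": [p.category.code for p in self.patterns],
                "category_name": [p.category.label for p in self.patterns],
                "raw": [p.raw for p in self.patterns],
                "normalized": [p.normalized for p in self.patterns],
                "is_regex": [p.is_regex for p in self.patterns],
            }
        )


def parse_lexicon_text(text: str) -> CdsLexicon:
    """Parse the packaged table dialect into a lexicon.

    Each non-empty line is ``<category name>\\t<patterns>`` with patterns
    separated by the two-character delimiter comma-then-space.  Commas inside
    a pattern (e.g. ``ok(e|é)?,? maar``) are never followed by a space in the
    printed table and therefore survive the split.  Pattern ids are assigned
    in reading order.
    """
    patterns: list[CdsPattern] = []
    seen: list[DistortionType] = []
    next_id = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            label, row = line.split("\t", 1)
        except ValueError:
            raise LexiconError(f"line {lineno}: expected '<category>\\t<patterns>'") from None
        category = DistortionType.from_label(label)
        if not row.strip():
            raise LexiconError(f"line {lineno}: empty pattern row for {label!r}")
        seen.append(category)
        for raw in row.split(", "):
            normalized = _normalize_pattern(raw)
            if not normalized:
                raise LexiconError(f"line {lineno}: empty pattern in row {label!r}")
            patterns.append(CdsPattern(id=next_id, category=category, raw=raw, normalized=normalized))
            next_id += 1
    lex = CdsLexicon(patterns=patterns)
    # refuse silently mis-ordered sources: category order must be canonical
    canonical = [c for c in DistortionType if c in seen]
    if seen != canonical:
        raise LexiconError("category rows are out of canonical order")
    return lex


def load_builtin_lexicon() -> CdsLexicon:
    """Load the packaged verbatim lexicon. Deterministic and idempotent."""
    try:
        text = (resources.files("cogmarker") / "data" / _RESOURCE).read_text(encoding="utf-8")
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise LexiconError(f"packaged lexicon resource missing: {exc}") from exc
    lex = parse_lexicon_text(text)
    if len({p.category for p in lex.patterns}) != len(DistortionType):
        raise LexiconError("packaged lexicon is corrupt: missing categories")
    return lex


def category_counts(lexicon: CdsLexicon) -> dict[str, int]:
    """Number of parsed patterns per category code, plus ``'total'``."""
    counts = {c.code: 0 for c in DistortionType}
    for p in lexicon.patterns:
        counts[p.category.code] += 1
    counts["total"] = len(lexicon.patterns)
    return counts
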