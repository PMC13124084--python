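"""Seeded synthetic chat corpora with known marker-injection structure.

Every message is built from a filler vocabulary that is *verified* at build
time to never trigger any lexicon pattern (several patterns consist of very
common Dutch words, so "neutral" text cannot be assumed neutral).  With a
configured per-role/category probability a message additionally embeds one
concrete realization of a lexicon pattern, produced by sampling the
pattern's own regex dialect.  Ground-truth injection labels are emitted
alongside, so the message-level indicator is an exact Bernoulli draw and
pipeline estimates can be checked against configured parameters
analytically.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, Message, Role, Session
from .errors import ConfigError, LexiconError
from .lexicon import CdsLexicon, CdsPattern, DistortionType, MatchOptions, load_builtin_lexicon
from .matcher import CdsMatcher

__all__ = [
    "SimulationConfig",
    "realize_pattern",
    "build_filler_vocabulary",
    "generate_corpus",
    "DEFAULT_FILLER_CANDIDATES",
]

#: neutral Dutch nouns/verbs sharing no word with any lexicon pattern;
#: screened again at build time — inclusion here is not trusted
DEFAULT_FILLER_CANDIDATES: tuple[str, ...] = (
    "fiets", "tafel", "lamp", "boom", "rivier", "wolk", "brood", "tuin",
    "venster", "straat", "muziek", "plant", "kast", "stoel", "appel",
    "kaas", "trein", "jas", "schoen", "klok", "spiegel", "deken", "vloer",
    "plafond", "keuken", "zolder", "kelder", "emmer", "bezem", "vork",
    "lepel", "bord", "pan", "fles", "krant", "potlood", "papier",
    "schaar", "touw", "wandelen", "fietsen", "tekenen", "zingen",
)

_GAP_TOKEN = "\x00"


def _parse_dialect(source: str) -> list:
    """Parse a normalized pattern (gap constructs replaced by a sentinel)
    into a small AST of sequence items."""
    items, i = _parse_sequence(source, 0, stop=None)
    return items


def _parse_sequence(s: str, i: int, stop: str | None) -> tuple[list, int]:
    items: list = []
    while i < len(s):
        ch = s[i]
        if stop is not None and ch in stop:
            break
        if ch == _GAP_TOKEN:
            items.append(("gap",))
            i += 1
        elif ch == "(":
            branches = []
            i += 1
            while True:
                branch, i = _parse_sequence(s, i, stop="|)")
                branches.append(branch)
                if i >= len(s):
                    raise LexiconError(f"unbalanced group in pattern: {s!r}")
                if s[i] == "|":
                    i += 1
                    continue
                i += 1  # consume ')'
                break
            optional = i < len(s) and s[i] == "?"
            if optional:
                i += 1
            items.append(("alt", branches, optional))
        elif ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise LexiconError(f"unbalanced class in pattern: {s!r}")
            chars = s[i + 1 : j]
            i = j + 1
            optional = i < len(s) and s[i] == "?"
            if optional:
                i += 1
            items.append(("class", chars, optional))
        else:
            i += 1
            optional = i < len(s) and s[i] == "?"
            if optional:
                i += 1
            items.append(("char", ch, optional))
    return items, i


def _realize_items(items: list, rng: np.random.Generator, gap_words: Sequence[str]) -> str:
    out = []
    for item in items:
        kind = item[0]
        if kind == "gap":
            if rng.random() < 0.5:
                out.append(" ")
            else:
                out.append(f" {gap_words[rng.integers(len(gap_words))]} ")
        elif kind == "alt":
            _, branches, optional = item
            if optional and rng.random() < 0.5:
                continue
            branch = branches[rng.integers(len(branches))]
            out.append(_realize_items(branch, rng, gap_words))
        elif kind == "class":
            _, chars, optional = item
            if optional and rng.random() < 0.5:
                continue
            out.append(chars[rng.integers(len(chars))])
        else:
            _, ch, optional = item
            if optional and rng.random() < 0.5:
                continue
            out.append(ch)
    return "".join(out)


def realize_pattern(
    pattern: CdsPattern,
    rng: np.random.Generator,
    gap_words: Sequence[str] = ("vandaag",),
) -> str:
    """Draw a concrete string accepted by the pattern's compiled matcher.

    Alternations and character classes are resolved uniformly at random,
    optional elements included with probability 1/2, and each gap construct
    resolved to a single space or to one gap word between spaces.
    """
    from .lexicon import _GAP  # shared definition of the printed gap construct

    source = _GAP.sub(_GAP_TOKEN, pattern.normalized)
    text = _realize_items(_parse_dialect(source), rng, gap_words)
    text = " ".join(text.split())
    if not text:
        raise LexiconError(f"pattern {pattern.id} realized to an empty string")
    return text


def build_filler_vocabulary(
    lexicon: CdsLexicon,
    candidates: Sequence[str] = DEFAULT_FILLER_CANDIDATES,
    options: MatchOptions | None = None,
    sweep: int = 200,
    seed: int = 0,
) -> list[str]:
    """Screen candidate filler words against the full lexicon.

    A candidate is rejected if, alone or juxtaposed (both orders) with any
    already-accepted word, it triggers any pattern.  A final seeded sweep of
    random filler sentences must produce zero matches; the accepted list is
    returned in candidate order.
    """
    matcher = CdsMatcher(lexicon, options)
    accepted: list[str] = []
    for word in candidates:
        probes = [word] + [f"{a} {word}" for a in accepted] + [f"{word} {a}" for a in accepted]
        if any(matcher.match_message(p)[0] for p in probes):
            continue
        accepted.append(word)
    if not accepted:
        raise ConfigError("filler vocabulary exhausted: every candidate matches the lexicon")
    rng = np.random.default_rng(seed)
    for _ in range(sweep):
        n = int(rng.integers(1, 11))
        sentence = " ".join(accepted[i] for i in rng.integers(len(accepted), size=n))
        if matcher.match_message(sentence)[0]:
            raise ConfigError(f"filler sweep failed: {sentence!r} matches the lexicon")
    return accepted


@dataclass
class SimulationConfig:
    """Parameters of a synthetic chat corpus.

    ``injection`` maps role code ("h"/"o") to a mapping of category code to
    per-message injection probability.  With ``independent_injection`` off
    (the default) at most one injection happens per message, so the overall
    indicator is an exact Bernoulli draw with the summed probability.
    """

    n_sessions: int = 100
    seed: int = 0
    mean_messages: dict[str, float] = field(default_factory=lambda: {"h": 10.0, "o": 9.0})
    system_rate: float = 0.5  # expected system messages per session
    injection: dict[str, dict[str, float]] = field(default_factory=dict)
    start_month: str = "2020-01"
    n_months: int = 12
    mean_sentence_words: float = 6.0
    independent_injection: bool = False

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if self.n_months < 1:
            raise ConfigError("n_months must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        codes = {c.code for c in DistortionType}
        for role, by_cat in self.injection.items():
            if role not in {"h", "o"}:
                raise ConfigError(f"injection role must be 'h' or 'o', got {role!r}")
            for cat, p in by_cat.items():
                if cat not in codes:
                    raise ConfigError(f"unknown category code {cat!r}")
                if not 0 <= p <= 1:
                    raise ConfigError(f"injection probability out of [0,1]: p({role},{cat})={p}")
            total = sum(by_cat.values())
            if not self.independent_injection and total > 1 + 1e-12:
                raise ConfigError(f"total injection probability for role {role!r} exceeds 1: {total}")

    @classmethod
    def from_dict(cls, obj: dict) -> "SimulationConfig":
        return cls(**obj)

    def to_dict(self) -> dict:
        return {
            "n_sessions": self.n_sessions,
            "seed": self.seed,
            "mean_messages": dict(self.mean_messages),
            "system_rate": self.system_rate,
            "injection": {r: dict(m) for r, m in self.injection.items()},
            "start_month": self.start_month,
            "n_months": self.n_months,
            "mean_sentence_words": self.mean_sentence_words,
            "independent_injection": self.independent_injection,
        }


def _window_days(start_month: str, n_months: int) -> tuple[dt.date, int]:
    year, month = (int(x) for x in start_month.split("-"))
    start = dt.date(year, month, 1)
    total = month - 1 + n_months
    end = dt.date(year + total // 12, total % 12 + 1, 1)
    return start, (end - start).days


def _interleave_roles(n_h: int, n_o: int, n_b: int, rng: np.random.Generator) -> list[Role]:
    roles: list[Role] = []
    h, o = n_h, n_o
    turn = Role.HELP_SEEKER
    while h > 0 or o > 0:
        if turn is Role.HELP_SEEKER and h > 0:
            roles.append(Role.HELP_SEEKER)
            h -= 1
        elif turn is Role.COUNSELOR and o > 0:
            roles.append(Role.COUNSELOR)
            o -= 1
        turn = Role.COUNSELOR if turn is Role.HELP_SEEKER else Role.HELP_SEEKER
    for _ in range(n_b):
        pos = int(rng.integers(0, len(roles) + 1))
        roles.insert(pos, Role.SYSTEM)
    return roles


def generate_corpus(
    cfg: SimulationConfig, lexicon: CdsLexicon | None = None
) -> tuple[Corpus, pd.DataFrame]:
    """Generate a seeded chat-mode corpus plus ground-truth labels.

    Sessions alternate help-seeker and counselor messages with system
    messages inserted at the configured rate; start dates are uniform over
    the configured month window.  The ground-truth frame has one row per
    message with columns session_id, msg_index, role, injected,
    category_code, pattern_id.
    """
    lexicon = lexicon or load_builtin_lexicon()
    rng = np.random.default_rng(cfg.seed)
    filler = build_filler_vocabulary(lexicon, seed=cfg.seed)
    by_cat = {c.code: lexicon.by_category[c] for c in DistortionType}
    start, n_days = _window_days(cfg.start_month, cfg.n_months)

    def filler_sentence() -> list[str]:
        n = 1 + int(rng.poisson(max(cfg.mean_sentence_words - 1, 0)))
        return [filler[i] for i in rng.integers(len(filler), size=n)]

    def injected_categories(role_code: str) -> list[str]:
        table = cfg.injection.get(role_code, {})
        if not table:
            return []
        cats = sorted(table)
        if cfg.independent_injection:
            return [c for c in cats if rng.random() < table[c]]
        u = rng.random()
        acc = 0.0
        for c in cats:
            acc += table[c]
            if u < acc:
                return [c]
        return []

    sessions = []
    truth_rows = []
    for s_idx in range(cfg.n_sessions):
        sid = f"s{s_idx:06d}"
        start_date = start + dt.timedelta(days=int(rng.integers(n_days)))
        n_h = int(rng.poisson(cfg.mean_messages.get("h", 0.0)))
        n_o = int(rng.poisson(cfg.mean_messages.get("o", 0.0)))
        n_b = int(rng.poisson(cfg.system_rate))
        roles = _interleave_roles(n_h, n_o, n_b, rng)
        messages = []
        t = 0.0
        for idx, role in enumerate(roles):
            t += float(rng.exponential(30.0))
            if role is Role.SYSTEM:
                messages.append(Message(role=role, t=t, text="systeembericht geregistreerd"))
                continue
            words = filler_sentence()
            cats = injected_categories(role.value)
            pattern_ids = []
            for cat in cats:
                pattern = by_cat[cat][rng.integers(len(by_cat[cat]))]
                realization = realize_pattern(pattern, rng, gap_words=filler)
                pos = int(rng.integers(0, len(words) + 1))
                words = words[:pos] + [realization] + words[pos:]
                pattern_ids.append(pattern.id)
            messages.append(Message(role=role, t=t, text=" ".join(words)))
            truth_rows.append(
                {
                    "session_id": sid,
                    "msg_index": idx,
                    "role": role.value,
                    "injected": int(bool(cats)),
                    "category_code": ";".join(cats),
                    "pattern_id": ";".join(str(i) for i in pattern_ids),
                }
            )
        sessions.append(Session(session_id=sid, start_date=start_date, messages=messages))
    truth = pd.DataFrame(
        truth_rows,
        columns=["session_id", "msg_index", "role", "injected", "category_code", "pattern_id"],
    )
    return Corpus(sessions=sessions, mode="chat"), truth
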