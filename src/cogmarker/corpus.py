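"""Data model and I/O for chat sessions, timelines, and sentence corpora.

Three corpus modes share one container:

``chat``
    sessions of role-tagged, time-stamped messages;
``timeline``
    one session per individual, messages are that individual's posts;
``sentence_collection``
    a single degenerate session whose messages are sentences (role ``h``,
    ``t = 0``).
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import CorpusFormatError

__all__ = [
    "Role",
    "Message",
    "Session",
    "Corpus",
    "read_sessions_jsonl",
    "read_sessions_csv",
    "read_sentence_corpus",
    "write_sessions_jsonl",
    "write_sessions_csv",
    "write_sentence_corpus",
    "exclude_system_messages",
]


class Role(enum.Enum):
    HELP_SEEKER = "h"
    COUNSELOR = "o"
    SYSTEM = "b"

    @classmethod
    def parse(cls, value: str) -> "Role":
        key = str(value).strip().lower().replace("_", " ")
        aliases = {
            "h": cls.HELP_SEEKER,
            "help seeker": cls.HELP_SEEKER,
            "helpseeker": cls.HELP_SEEKER,
            "o": cls.COUNSELOR,
            "counselor": cls.COUNSELOR,
            "b": cls.SYSTEM,
            "system": cls.SYSTEM,
        }
        try:
            return aliases[key]
        except KeyError:
            raise CorpusFormatError(f"unknown role value: {value!r}") from None


@dataclass(frozen=True)
class Message:
    role: Role
    t: float  # seconds elapsed from session start
    text: str

    def __post_init__(self) -> None:
        if self.t < 0:
            raise CorpusFormatError(f"negative message time: {self.t}")


@dataclass
class Session:
    session_id: str
    start_date: dt.date
    messages: list[Message] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.session_id:
            raise CorpusFormatError("session_id must be non-empty")


@dataclass
class Corpus:
    sessions: list[Session] = field(default_factory=list)
    mode: str = "chat"  # chat | timeline | sentence_collection

    def n_messages(self) -> int:
        return sum(len(s.messages) for s in self.sessions)


def _parse_date(value: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        raise CorpusFormatError(f"unparseable start_date: {value!r}") from None


def _sorted_messages(messages: list[Message]) -> list[Message]:
    # stable: ties keep input order
    return sorted(messages, key=lambda m: m.t)


def read_sessions_jsonl(path: str | Path, mode: str = "chat") -> Corpus:
    """Read one JSON object per line:
    ``{"session_id", "start_date", "messages": [{"role", "t", "text"}]}``.
    Messages are sorted by ``t`` (stable)."""
    sessions = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            try:
                messages = [
                    Message(role=Role.parse(m["role"]), t=float(m["t"]), text=str(m["text"]))
                    for m in obj["messages"]
                ]
                session = Session(
                    session_id=str(obj["session_id"]),
                    start_date=_parse_date(obj["start_date"]),
                    messages=_sorted_messages(messages),
                )
            except KeyError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: missing field {exc}") from exc
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from None
            sessions.append(session)
    return Corpus(sessions=sessions, mode=mode)


_CSV_COLUMNS = ["session_id", "start_date", "role", "t", "text"]


def read_sessions_csv(path: str | Path, mode: str = "chat") -> Corpus:
    """Read a long-format CSV (columns session_id, start_date, role, t, text;
    RFC-4180 quoting). Produces the same corpus as the equivalent JSONL."""
    groups: dict[str, tuple[dt.date, list[Message]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return Corpus(sessions=[], mode=mode)
        for col in _CSV_COLUMNS:
            if col not in reader.fieldnames:
                raise CorpusFormatError(f"{path}: missing column {col!r}")
        for row in reader:
            sid = row["session_id"]
            msg = Message(role=Role.parse(row["role"]), t=float(row["t"]), text=row["text"])
            if sid not in groups:
                groups[sid] = (_parse_date(row["start_date"]), [])
                order.append(sid)
            groups[sid][1].append(msg)
    sessions = [
        Session(session_id=sid, start_date=groups[sid][0], messages=_sorted_messages(groups[sid][1]))
        for sid in order
    ]
    return Corpus(sessions=sessions, mode=mode)


def read_sentence_corpus(path: str | Path) -> Corpus:
    """Read a plain-text corpus, one sentence per line; blank lines dropped.
    Returns a single-session corpus in ``sentence_collection`` mode."""
    messages = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sentence = line.rstrip("\n")
            if not sentence.strip():
                continue
            messages.append(Message(role=Role.HELP_SEEKER, t=0.0, text=sentence))
    session = Session(session_id="sentences", start_date=dt.date(1970, 1, 1), messages=messages)
    return Corpus(sessions=[session], mode="sentence_collection")


def write_sessions_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus.sessions:
            obj = {
                "session_id": s.session_id,
                "start_date": s.start_date.isoformat(),
                "messages": [{"role": m.role.value, "t": m.t, "text": m.text} for m in s.messages],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def write_sessions_csv(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for s in corpus.sessions:
            for m in s.messages:
                writer.writerow([s.session_id, s.start_date.isoformat(), m.role.value, m.t, m.text])


def write_sentence_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus.sessions:
            for m in s.messages:
                fh.write(m.text.replace("\n", " ") + "\n")


def exclude_system_messages(corpus: Corpus) -> Corpus:
    """Drop all system (role ``b``) messages, leaving session structure —
    including sessions rendered empty — untouched."""
    sessions = [
        Session(
            session_id=s.session_id,
            start_date=s.start_date,
            messages=[m for m in s.messages if m.role is not Role.SYSTEM],
        )
        for s in corpus.sessions
    ]
    return Corpus(sessions=sessions, mode=corpus.mode)
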