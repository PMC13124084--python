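import datetime as dt

import pytest

from cogmarker.corpus import Corpus, Message, Role, Session
from cogmarker.lexicon import MatchOptions, compile_pattern, load_builtin_lexicon, normalize_text
from cogmarker.matcher import CdsMatcher


@pytest.fixture(scope="session")
def lexicon():
    return load_builtin_lexicon()


@pytest.fixture(scope="session")
def matcher(lexicon):
    return CdsMatcher(lexicon)


@pytest.fixture(scope="session")
def naive_matcher(lexicon):
    """Independent oracle: per-pattern loop over individually compiled
    patterns, no category screen, no shared state with CdsMatcher."""
    compiled = [(p, compile_pattern(p, MatchOptions())) for p in lexicon.patterns]

    def match(text, patterns=None):
        wanted = None if patterns is None else {p.id for p in patterns}
        norm = normalize_text(text)
        if not norm:
            return 0, []
        ids = sorted(
            p.id for p, rx in compiled
            if (wanted is None or p.id in wanted) and rx.search(norm)
        )
        return (1 if ids else 0), ids

    return match


def make_session(session_id, roles_texts, start=dt.date(2020, 3, 1)):
    """Build a session from (role_code, text) pairs with 10-second spacing."""
    messages = [
        Message(role=Role(code), t=10.0 * i, text=text)
        for i, (code, text) in enumerate(roles_texts)
    ]
    return Session(session_id=session_id, start_date=start, messages=messages)


@pytest.fixture
def tiny_corpus():
    return Corpus(
        sessions=[
            make_session("a", [("h", "omdat ik moe ben"), ("o", "fiets tafel"), ("b", "systeem")]),
            make_session("b", [("h", "boom rivier"), ("h", "dat zou kunnen"), ("o", "dat zou kunnen")]),
        ],
        mode="chat",
    )
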