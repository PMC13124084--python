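import datetime as dt
import json
import tempfile

import pytest
from hypothesis import given, settings, strategies as st

from cogmarker.corpus import (
    Corpus,
    Message,
    Role,
    Session,
    exclude_system_messages,
    read_sentence_corpus,
    read_sessions_csv,
    read_sessions_jsonl,
    write_sentence_corpus,
    write_sessions_csv,
    write_sessions_jsonl,
)
from cogmarker.errors import CorpusFormatError

from conftest import make_session


def _write_jsonl(path, sessions):
    with open(path, "w", encoding="utf-8") as fh:
        for s in sessions:
            fh.write(json.dumps(s) + "\n")


class TestRole:
    @pytest.mark.parametrize("value,expected", [
        ("h", Role.HELP_SEEKER), ("help seeker", Role.HELP_SEEKER),
        ("o", Role.COUNSELOR), ("Counselor", Role.COUNSELOR),
        ("b", Role.SYSTEM), ("system", Role.SYSTEM),
    ])
    def test_aliases(self, value, expected):
        assert Role.parse(value) is expected

    def test_unknown_role(self):
        with pytest.raises(CorpusFormatError, match="'x'"):
            Role.parse("x")


class TestJsonl:
    def test_basic(self, tmp_path):
        path = tmp_path / "c.jsonl"
        _write_jsonl(path, [
            {"session_id": "a", "start_date": "2020-01-02",
             "messages": [{"role": "h", "t": 0, "text": "een"},
                          {"role": "o", "t": 5, "text": "twee"},
                          {"role": "b", "t": 9, "text": "drie"}]},
            {"session_id": "b", "start_date": "2020-02-01",
             "messages": [{"role": "h", "t": 0, "text": "x"},
                          {"role": "h", "t": 1, "text": "y"},
                          {"role": "o", "t": 2, "text": "z"}]},
        ])
        corpus = read_sessions_jsonl(path)
        assert corpus.mode == "chat"
        assert len(corpus.sessions) == 2
        assert corpus.n_messages() == 6
        assert corpus.sessions[0].start_date == dt.date(2020, 1, 2)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text('{"session_id": "a", "start_date": "2020-01-01", "messages": []}\n{oops\n')
        with pytest.raises(CorpusFormatError, match=":2"):
            read_sessions_jsonl(path)

    def test_unknown_role_reports_value_and_line(self, tmp_path):
        path = tmp_path / "c.jsonl"
        _write_jsonl(path, [{"session_id": "a", "start_date": "2020-01-01",
                             "messages": [{"role": "x", "t": 0, "text": ""}]}])
        with pytest.raises(CorpusFormatError, match="'x'"):
            read_sessions_jsonl(path)

    def test_messages_sorted_stably_by_t(self, tmp_path):
        path = tmp_path / "c.jsonl"
        _write_jsonl(path, [{"session_id": "a", "start_date": "2020-01-01",
                             "messages": [{"role": "h", "t": 7, "text": "late"},
                                          {"role": "o", "t": 3, "text": "first-tie"},
                                          {"role": "h", "t": 3, "text": "second-tie"}]}])
        msgs = read_sessions_jsonl(path).sessions[0].messages
        assert [m.text for m in msgs] == ["first-tie", "second-tie", "late"]


class TestCsv:
    def test_missing_column(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("session_id,start_date,role,text\n")
        with pytest.raises(CorpusFormatError, match="'t'"):
            read_sessions_csv(path)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("session_id,start_date,role,t,text\n")
        assert read_sessions_csv(path).sessions == []

    def test_quoted_text_with_comma_and_newline(self, tmp_path):
        corpus = Corpus(sessions=[make_session("a", [("h", "hallo, wereld\ntweede regel")])])
        path = tmp_path / "c.csv"
        write_sessions_csv(corpus, path)
        back = read_sessions_csv(path)
        assert back.sessions[0].messages[0].text == "hallo, wereld\ntweede regel"


class TestSentenceCorpus:
    def test_blank_lines_dropped(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("een zin\ntwee\n\ndrie\nvier\n", encoding="utf-8")
        corpus = read_sentence_corpus(path)
        assert corpus.mode == "sentence_collection"
        assert len(corpus.sessions) == 1
        assert corpus.n_messages() == 4

    def test_whitespace_only_line_dropped(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("een\n   \ntwee\n", encoding="utf-8")
        assert read_sentence_corpus(path).n_messages() == 2

    def test_empty_file_degenerate(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("")
        corpus = read_sentence_corpus(path)
        assert len(corpus.sessions) == 1
        assert corpus.n_messages() == 0

    def test_sentences_are_role_h_at_t0(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("a\nb\n")
        for m in read_sentence_corpus(path).sessions[0].messages:
            assert m.role is Role.HELP_SEEKER
            assert m.t == 0.0


class TestExcludeSystem:
    def test_example(self):
        corpus = Corpus(sessions=[make_session("a", [("h", "x"), ("b", "y"), ("o", "z")])])
        out = exclude_system_messages(corpus)
        assert [m.role for m in out.sessions[0].messages] == [Role.HELP_SEEKER, Role.COUNSELOR]

    def test_identity_without_system(self, tiny_corpus):
        once = exclude_system_messages(tiny_corpus)
        twice = exclude_system_messages(once)
        assert once == twice

    def test_all_system_session_retained_empty(self):
        corpus = Corpus(sessions=[make_session("a", [("b", "x"), ("b", "y")])])
        out = exclude_system_messages(corpus)
        assert len(out.sessions) == 1
        assert out.sessions[0].messages == []

    def test_h_and_o_counts_preserved(self, tiny_corpus):
        def count(c, role):
            return sum(1 for s in c.sessions for m in s.messages if m.role is role)

        out = exclude_system_messages(tiny_corpus)
        assert count(out, Role.HELP_SEEKER) == count(tiny_corpus, Role.HELP_SEEKER)
        assert count(out, Role.COUNSELOR) == count(tiny_corpus, Role.COUNSELOR)
        assert count(out, Role.SYSTEM) == 0


class TestRoundTrips:
    def test_jsonl_csv_equivalence(self, tiny_corpus, tmp_path):
        write_sessions_jsonl(tiny_corpus, tmp_path / "c.jsonl")
        write_sessions_csv(tiny_corpus, tmp_path / "c.csv")
        assert read_sessions_jsonl(tmp_path / "c.jsonl") == read_sessions_csv(tmp_path / "c.csv")

    def test_jsonl_round_trip_conserves_messages(self, tiny_corpus, tmp_path):
        write_sessions_jsonl(tiny_corpus, tmp_path / "c.jsonl")
        back = read_sessions_jsonl(tmp_path / "c.jsonl")
        assert back == tiny_corpus

    def test_sentence_round_trip(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("een zin\ntwee zinnen\n", encoding="utf-8")
        corpus = read_sentence_corpus(path)
        write_sentence_corpus(corpus, tmp_path / "s2.txt")
        assert read_sentence_corpus(tmp_path / "s2.txt") == corpus


class TestFormatEquivalenceProperty:
    # long-format CSV cannot represent a session with zero messages, so the
    # equivalence property is stated over non-empty sessions
    text_strategy = st.text(
        alphabet=st.characters(blacklist_categories=("Cs",)), max_size=40
    )

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.sampled_from(["h", "o", "b"]), text_strategy),
                min_size=1,
                max_size=5,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_jsonl_and_csv_read_identically(self, sessions_spec):
        corpus = Corpus(
            sessions=[
                make_session(f"s{i}", pairs) for i, pairs in enumerate(sessions_spec)
            ]
        )
        with tempfile.TemporaryDirectory() as d:
            jsonl, csvf = f"{d}/c.jsonl", f"{d}/c.csv"
            write_sessions_jsonl(corpus, jsonl)
            write_sessions_csv(corpus, csvf)
            from_jsonl = read_sessions_jsonl(jsonl)
            from_csv = read_sessions_csv(csvf)
        assert from_jsonl == from_csv == corpus


class TestValidation:
    def test_negative_time_rejected(self):
        with pytest.raises(CorpusFormatError):
            Message(role=Role.HELP_SEEKER, t=-1.0, text="x")

    def test_empty_session_id_rejected(self):
        with pytest.raises(CorpusFormatError):
            Session(session_id="", start_date=dt.date(2020, 1, 1))

    def test_empty_text_retained(self):
        s = make_session("a", [("h", "")])
        assert s.messages[0].text == ""
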