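"""Corpus loading, keyword filtering, geocoding and partitioning."""

import json
from datetime import date

import pytest

from peolc_topics.corpus import (
    EmptyCorpusError,
    TweetRecord,
    assign_country,
    default_filter_terms,
    dedupe_texts,
    load_tweets,
    match_peolc,
    monthly_counts,
    partition_by_period,
    share,
)

from conftest import dt


def _write_jsonl(path, objs):
    with open(path, "w", encoding="utf-8") as fh:
        for o in objs:
            fh.write((o if isinstance(o, str) else json.dumps(o)) + "\n")


def _tweet(i, text="hello hospice", created="Mon Dec 07 10:00:00 +0000 2020",
           lang="en", location="Boston, Massachusetts"):
    return {
        "id_str": str(i),
        "full_text": text,
        "created_at": created,
        "lang": lang,
        "user": {"location": location},
    }


class TestLoadTweets:
    def test_well_formed_lines_load(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, [_tweet(i) for i in range(3)])
        records, diags = load_tweets(p)
        assert len(records) == 3
        assert diags.n_loaded == 3
        assert records[0].created_at == dt(2020, 12, 7, 10)
        assert records[0].country == "US"

    def test_non_english_excluded_and_counted(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, [_tweet(0), _tweet(1, lang="fr"), _tweet(2)])
        records, diags = load_tweets(p)
        assert len(records) == 2
        assert diags.n_non_english == 1

    def test_malformed_date_skipped(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, [_tweet(0), _tweet(1, created="not a date")])
        records, diags = load_tweets(p)
        assert len(records) == 1
        assert diags.n_bad_date == 1

    def test_malformed_json_skipped(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, [_tweet(0), "{not json"])
        records, diags = load_tweets(p)
        assert len(records) == 1
        assert diags.n_malformed == 1

    def test_no_well_formed_lines_raises(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, ["{broken", "also broken"])
        with pytest.raises(EmptyCorpusError):
            load_tweets(p)

    def test_missing_file_raises_oserror(self, tmp_path):
        with pytest.raises(OSError):
            load_tweets(tmp_path / "nope.jsonl")


class TestMatchPeolc:
    def test_bundled_terms_unique_and_nonempty(self):
        terms = default_filter_terms()
        assert len(terms) == len({t.lower() for t in terms})
        assert all(t.strip() for t in terms)

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Our palliative care team is hiring", True),
            ("COVID cases are rising again", False),
            ("join the #eolc chat", True),
            ("PALLIATIVE  CARE matters", True),  # case + collapsed spaces
            ("thinking about end of life decisions", True),
            ("", False),
        ],
    )
    def test_filter_semantics(self, text, expected):
        assert match_peolc(text) is expected

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            match_peolc("anything", ["hospice", " "])
        with pytest.raises(ValueError):
            match_peolc("anything", [])


class TestAssignCountry:
    @pytest.mark.parametrize(
        "loc,expected",
        [
            ("Toronto, Ontario", "CA"),
            ("somewhere on earth", None),
            ("London / New York", None),  # conflicting countries
            ("London, England", "GB"),
            ("Los Angeles, CA", "US"),  # CA reads as California here
            ("Scotland", "GB"),
            ("Vancouver, BC", "CA"),
            ("NYC", "US"),
            ("", None),
        ],
    )
    def test_gazetteer_resolution(self, loc, expected):
        assert assign_country(loc) == expected


def _records_on(dates, country="US"):
    return [
        TweetRecord(id=str(i), text="t", created_at=d, country=country)
        for i, d in enumerate(dates)
    ]


class TestPartitionByPeriod:
    def test_boundary_day_is_post(self):
        recs = _records_on([dt(2020, 12, 9, 23, 59), dt(2020, 12, 10, 0, 0)])
        split = partition_by_period(recs, "US", date(2020, 12, 10))
        assert (split.n_pre, split.n_post) == (1, 1)

    def test_other_countries_excluded_and_conserved(self):
        recs = _records_on([dt(2020, 11, 1), dt(2020, 12, 25)]) + _records_on(
            [dt(2020, 11, 2)], country="GB"
        )
        split = partition_by_period(recs, "US", date(2020, 12, 10))
        assert split.n_total == 2
        assert split.n_pre + split.n_post == 2

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            split = partition_by_period([], "US", date(2020, 12, 10))
        assert split.n_total == 0
        assert split.percentages() == (0.0, 0.0)

    def test_us_study_counts_reproduce_printed_shares(self):
        pre = _records_on([dt(2020, 11, 1)] * 1739)
        post = _records_on([dt(2021, 1, 1)] * 2394)
        split = partition_by_period(pre + post, "US", date(2020, 12, 10))
        assert split.n_total == 4133
        assert split.percentages() == (42.08, 57.92)


class TestShare:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (1739, 4133, 2, 42.08),
            (2394, 4133, 2, 57.92),
            (1, 8, 2, 12.5),
            (1, 800, 2, 0.13),  # 0.125 rounds half-up to 0.13
            (349, 895, 0, 39.0),
        ],
    )
    def test_half_up_rounding(self, num, den, decimals, expected):
        assert share(num, den, decimals) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            share(1, 0)


class TestMonthlyCounts:
    def test_single_month(self):
        recs = _records_on([dt(2020, 12, 1), dt(2020, 12, 15), dt(2020, 12, 31)])
        counts, props = monthly_counts(recs)
        assert counts == {(2020, 12): 3}
        assert props[(2020, 12)] == {"US": 1.0}

    def test_empty_input(self):
        counts, props = monthly_counts([])
        assert counts == {} and props == {}

    def test_two_months_two_countries_recount(self):
        recs = (
            _records_on([dt(2020, 11, 3)] * 2, "US")
            + _records_on([dt(2020, 12, 3)] * 3, "US")
            + _records_on([dt(2020, 11, 9)] * 4, "GB")
            + _records_on([dt(2020, 12, 9)] * 5, "GB")
        )
        counts, props = monthly_counts(recs)
        # brute-force recount
        assert counts == {(2020, 11): 6, (2020, 12): 8}
        assert sum(counts.values()) == len(recs)
        for month, by_cc in props.items():
            assert sum(by_cc.values()) == pytest.approx(1.0, abs=1e-9)
        assert props[(2020, 11)]["US"] == pytest.approx(2 / 6)

    def test_unreported_country_goes_to_other(self):
        recs = _records_on([dt(2020, 11, 3)], country="FR")
        _, props = monthly_counts(recs)
        assert props[(2020, 11)] == {"other": 1.0}


def test_dedupe_keeps_earliest_of_each_text():
    recs = [
        TweetRecord(id="2", text="same", created_at=dt(2020, 11, 2)),
        TweetRecord(id="1", text="same", created_at=dt(2020, 11, 1)),
        TweetRecord(id="3", text="other", created_at=dt(2020, 11, 3)),
    ]
    out = dedupe_texts(recs)
    assert [r.id for r in out] == ["1", "3"]
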