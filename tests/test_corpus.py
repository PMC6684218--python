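"""Post I/O, alias matching and drug-corpus construction."""

from datetime import date

import pytest

from adrsignal.corpus import (
    DrugCorpus,
    Post,
    PostRecordError,
    build_drug_corpus,
    compile_drug_matcher,
    find_drug_mentions,
    load_alias_table,
    merge_corpora,
    read_posts,
    write_posts,
)

ALIASES = ["erlotinib", "tarceva"]


class TestPostIO:
    @pytest.mark.parametrize("fmt", ["jsonl", "tsv"])
    def test_round_trip_preserves_records(self, toy_posts, tmp_path, fmt):
        path = tmp_path / f"posts.{fmt}"
        write_posts(toy_posts, path, format=fmt)
        back = read_posts(path, format=fmt)
        assert back == toy_posts

    def test_tsv_round_trip_escapes_body_tabs_and_newlines(self, tmp_path):
        post = Post("p1", "u1", date(2014, 1, 1), "line one\nline\ttwo")
        path = tmp_path / "posts.tsv"
        write_posts([post], path, format="tsv")
        assert read_posts(path, format="tsv") == [post]

    def test_missing_field_error_names_line(self, tmp_path):
        path = tmp_path / "posts.jsonl"
        path.write_text(
            '{"post_id":"p1","user_id":"u1","created_at":"2014-01-01","body":"a"}\n'
            '{"post_id":"p2","user_id":"u2","created_at":"2014-01-02","body":"b"}\n'
            '{"post_id":"p3","created_at":"2014-01-03","body":"c"}\n'
        )
        with pytest.raises(PostRecordError, match="line 3") as exc:
            read_posts(path)
        assert "user_id" in str(exc.value)

    def test_unparseable_date_error_names_line(self, tmp_path):
        path = tmp_path / "posts.jsonl"
        path.write_text(
            '{"post_id":"p1","user_id":"u1","created_at":"not-a-date","body":"a"}\n'
        )
        with pytest.raises(PostRecordError, match="line 1"):
            read_posts(path)

    def test_date_outside_configured_range_rejected(self, tmp_path):
        path = tmp_path / "posts.jsonl"
        path.write_text(
            '{"post_id":"p1","user_id":"u1","created_at":"1999-12-31","body":"a"}\n'
        )
        with pytest.raises(PostRecordError, match="range"):
            read_posts(path)

    def test_duplicate_post_id_rejected(self, tmp_path):
        path = tmp_path / "posts.jsonl"
        path.write_text(
            '{"post_id":"p1","user_id":"u1","created_at":"2014-01-01","body":"a"}\n'
            '{"post_id":"p1","user_id":"u2","created_at":"2014-01-02","body":"b"}\n'
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_posts(path)

    def test_alias_table_lowercases_and_groups(self, tmp_path):
        path = tmp_path / "aliases.tsv"
        path.write_text("erlotinib\terlotinib\nerlotinib\tTarceva\nnivolumab\tOpdivo\n")
        table = load_alias_table(path)
        assert table == {"erlotinib": ["erlotinib", "tarceva"], "nivolumab": ["opdivo"]}


class TestMatcher:
    def test_case_insensitive_brand_match(self):
        matcher = compile_drug_matcher(ALIASES)
        matches = find_drug_mentions(matcher, "Started Tarceva today")
        assert matches == [(8, 15, "Tarceva")]

    def test_word_boundary_blocks_substring(self):
        matcher = compile_drug_matcher(ALIASES)
        assert find_drug_mentions(matcher, "erlotinibx") == []
        assert find_drug_mentions(matcher, "xerlotinib") == []

    def test_multiple_occurrences(self):
        matcher = compile_drug_matcher(ALIASES)
        assert len(find_drug_mentions(matcher, "tarceva then more tarceva")) == 2

    def test_punctuation_is_a_boundary(self):
        matcher = compile_drug_matcher(ALIASES)
        assert len(find_drug_mentions(matcher, "on erlotinib, then (tarceva).")) == 2

    def test_empty_alias_list_rejected(self):
        with pytest.raises(ValueError):
            compile_drug_matcher([])


def _brute_force_mentions(body: str, aliases) -> bool:
    """Independent oracle: substring scan + manual boundary check."""
    low = body.lower()
    for alias in aliases:
        start = 0
        while (i := low.find(alias, start)) != -1:
            before = low[i - 1] if i > 0 else " "
            after = low[i + len(alias)] if i + len(alias) < len(low) else " "
            if not before.isalnum() and not after.isalnum():
                return True
            start = i + 1
    return False


class TestCorpusBuild:
    def test_corpus_contains_exactly_matching_posts(self, toy_posts):
        matcher = compile_drug_matcher(ALIASES)
        corpus = build_drug_corpus(toy_posts, matcher, "erlotinib")
        assert corpus.post_ids == {"p1", "p2", "p5"}
        assert len(corpus) == 3

    def test_membership_matches_brute_force_oracle(self, small_bundle):
        config = small_bundle.config
        for drug in list(config.drug_ids)[:3]:
            matcher = compile_drug_matcher(config.aliases[drug])
            corpus = build_drug_corpus(small_bundle.posts, matcher, drug)
            expected = {
                p.post_id
                for p in small_bundle.posts
                if _brute_force_mentions(p.body, config.aliases[drug])
            }
            assert corpus.post_ids == expected

    def test_membership_soundness(self, toy_posts):
        matcher = compile_drug_matcher(ALIASES)
        corpus = build_drug_corpus(toy_posts, matcher, "erlotinib")
        for post in corpus.posts:
            assert matcher.search(post.body) is not None

    def test_no_match_gives_empty_corpus(self, toy_posts):
        matcher = compile_drug_matcher(["nivolumab"])
        assert len(build_drug_corpus(toy_posts, matcher, "nivolumab")) == 0

    def test_every_post_matching_gives_identity(self, toy_posts):
        matcher = compile_drug_matcher(["tarceva", "erlotinib", "nothing", "drug"])
        corpus = build_drug_corpus(toy_posts, matcher, "stopwords")
        assert len(corpus) == len(toy_posts)


class TestMerge:
    def _corpus(self, drug_id, posts):
        return DrugCorpus(drug_id=drug_id, posts=posts)

    def test_union_deduplicates_shared_post(self, toy_posts):
        a = self._corpus("a", toy_posts[:3])  # p1 p2 p3
        b = self._corpus("b", toy_posts[2:])  # p3 p4 p5 — shares p3
        merged = merge_corpora([a, b], "class")
        assert len(merged) == 5
        assert merged.drug_id == "class"

    def test_merge_single_corpus_is_identity(self, toy_posts):
        a = self._corpus("a", toy_posts)
        assert merge_corpora([a], "class").post_ids == a.post_ids

    def test_merge_commutative_as_sets(self, toy_posts):
        a = self._corpus("a", toy_posts[:3])
        b = self._corpus("b", toy_posts[2:])
        assert merge_corpora([a, b], "c").post_ids == merge_corpora([b, a], "c").post_ids

    def test_merge_idempotent(self, toy_posts):
        a = self._corpus("a", toy_posts[:3])
        b = self._corpus("b", toy_posts[2:])
        once = merge_corpora([a, b], "c")
        twice = merge_corpora([once], "c")
        assert twice.post_ids == once.post_ids

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_corpora([], "c")
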