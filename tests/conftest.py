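from datetime import date

import pytest

from adrsignal.corpus import Post
from adrsignal.normalize import build_index
from adrsignal.synth import default_config, generate_corpus, lexicon_fixture_entries


@pytest.fixture(scope="session")
def fixture_lexicon():
    return lexicon_fixture_entries()


@pytest.fixture(scope="session")
def fixture_index(fixture_lexicon):
    return build_index(fixture_lexicon)


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted-association corpus shared by read-only tests."""
    config = default_config(n_users=400, seed=7).plant("albanib", "hypohidrosis", 0.24)
    return generate_corpus(config)


@pytest.fixture()
def toy_posts():
    texts = [
        ("p1", "u1", "2014-03-05", "Started Tarceva today and feeling hopeful."),
        ("p2", "u2", "2014-04-01", "my erlotinib dose went up. rash is back."),
        ("p3", "u1", "2014-05-20", "nothing new to report this week."),
        ("p4", "u3", "2014-06-11", "erlotinibx is not a drug name."),
        ("p5", "u4", "2014-07-02", "tarceva then more tarceva for me."),
    ]
    return [
        Post(post_id=a, user_id=b, created_at=date.fromisoformat(c), body=d)
        for a, b, c, d in texts
    ]
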