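"""Forum-post I/O and per-drug corpus construction.

A *drug corpus* is the set of posts containing at least one mention of any
alias (generic or brand name) of a drug of interest.  Matching is exact,
case-insensitive string matching at alphanumeric word boundaries — a post
containing ``erlotinibx`` does not match the alias ``erlotinib``.  Corpora
for drugs of the same class (e.g. the PD-1 inhibitors nivolumab and
pembrolizumab) can be merged, deduplicating posts by id so a post that
mentions both class members is counted once downstream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Post",
    "DrugCorpus",
    "PostRecordError",
    "read_posts",
    "write_posts",
    "load_alias_table",
    "compile_drug_matcher",
    "build_drug_corpus",
    "merge_corpora",
]

#: default validity window for post dates; configurable per call.
DEFAULT_DATE_RANGE = (date(2000, 1, 1), date(2099, 12, 31))

_REQUIRED_FIELDS = ("post_id", "user_id", "created_at", "body")


class PostRecordError(ValueError):
    """A malformed post record; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass(frozen=True)
class Post:
    """One forum post."""

    post_id: str
    user_id: str
    created_at: date
    body: str


@dataclass
class DrugCorpus:
    """Posts mentioning a drug (or any member of a drug class).

    ``provenance`` maps post_id to the alias surface that matched first.
    """

    drug_id: str
    posts: list[Post]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def post_ids(self) -> set[str]:
        return {p.post_id for p in self.posts}


def _parse_record(fields: dict, line_no: int, date_range) -> Post:
    for name in _REQUIRED_FIELDS:
        if name not in fields or fields[name] in (None, ""):
            raise PostRecordError(line_no, f"missing required field {name!r}")
    try:
        created = date.fromisoformat(str(fields["created_at"]))
    except ValueError as exc:
        raise PostRecordError(
            line_no, f"unparseable date {fields['created_at']!r}: {exc}"
        ) from None
    lo, hi = date_range
    if not (lo <= created <= hi):
        raise PostRecordError(
            line_no, f"date {created.isoformat()} outside allowed range [{lo}, {hi}]"
        )
    return Post(
        post_id=str(fields["post_id"]),
        user_id=str(fields["user_id"]),
        created_at=created,
        body=str(fields["body"]),
    )


_TSV_ESCAPES = {"\\\\": "\\", "\\t": "\t", "\\n": "\n"}


def _tsv_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _tsv_unescape(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text):
            pair = text[i : i + 2]
            if pair in _TSV_ESCAPES:
                out.append(_TSV_ESCAPES[pair])
                i += 2
                continue
        out.append(text[i])
        i += 1
    return "".join(out)


def read_posts(
    path: str | Path,
    format: str = "jsonl",
    date_range: tuple[date, date] = DEFAULT_DATE_RANGE,
) -> list[Post]:
    """Read posts from a line-delimited file.

    ``format`` is ``"jsonl"`` (one JSON object per line) or ``"tsv"``
    (header row ``post_id  user_id  created_at  body``; tabs/newlines in the
    body are backslash-escaped).  Records are returned in file order; any
    malformed record raises :class:`PostRecordError` naming its line.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    posts: list[Post] = []
    if format == "jsonl":
        for i, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise PostRecordError(i, f"invalid JSON: {exc}") from None
            posts.append(_parse_record(rec, i, date_range))
    elif format == "tsv":
        if not lines:
            return []
        header = lines[0].split("\t")
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            values = line.split("\t")
            if len(values) != len(header):
                raise PostRecordError(
                    i, f"expected {len(header)} fields, got {len(values)}"
                )
            rec = dict(zip(header, values))
            if "body" in rec:
                rec["body"] = _tsv_unescape(rec["body"])
            posts.append(_parse_record(rec, i, date_range))
    else:
        raise ValueError(f"unknown posts format {format!r}")
    seen: set[str] = set()
    for p in posts:
        if p.post_id in seen:
            raise ValueError(f"duplicate post_id {p.post_id!r}")
        seen.add(p.post_id)
    return posts


def write_posts(posts: Iterable[Post], path: str | Path, format: str = "jsonl") -> None:
    """Write posts in a format :func:`read_posts` round-trips."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for p in posts:
                fh.write(
                    json.dumps(
                        {
                            "post_id": p.post_id,
                            "user_id": p.user_id,
                            "created_at": p.created_at.isoformat(),
                            "body": p.body,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("post_id\tuser_id\tcreated_at\tbody\n")
            for p in posts:
                fh.write(
                    f"{p.post_id}\t{p.user_id}\t{p.created_at.isoformat()}"
                    f"\t{_tsv_escape(p.body)}\n"
                )
    else:
        raise ValueError(f"unknown posts format {format!r}")


def load_alias_table(path: str | Path) -> dict[str, list[str]]:
    """Load a two-column TSV (drug_id, alias) into drug_id → aliases.

    Aliases are lowercased at load; every drug must end up with at least one
    non-empty alias.
    """
    table: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"alias table line {i}: expected 2 columns, got {len(parts)}")
        drug_id, alias = parts[0].strip(), parts[1].strip().lower()
        if not alias:
            raise ValueError(f"alias table line {i}: empty alias")
        table.setdefault(drug_id, [])
        if alias not in table[drug_id]:
            table[drug_id].append(alias)
    if not table:
        raise ValueError("alias table is empty")
    return table


def compile_drug_matcher(aliases: Sequence[str], case_sensitive: bool = False):
    """Compile aliases into a regex matcher at alphanumeric word boundaries.

    Returns a compiled pattern whose ``finditer`` yields non-overlapping
    alias occurrences with character offsets into the searched text.  Longer
    aliases take precedence at the same start position.
    """
    aliases = [a for a in aliases if a]
    if not aliases:
        raise ValueError("at least one non-empty alias is required")
    ordered = sorted(set(aliases), key=lambda a: (-len(a), a))
    body = "|".join(re.escape(a) for a in ordered)
    pattern = rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])"
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(pattern, flags)


def find_drug_mentions(matcher: re.Pattern, body: str) -> list[tuple[int, int, str]]:
    """All non-overlapping alias matches as (start, end, surface) tuples."""
    return [(m.start(), m.end(), m.group(0)) for m in matcher.finditer(body)]


def build_drug_corpus(
    posts: Sequence[Post], matcher: re.Pattern, drug_id: str
) -> DrugCorpus:
    """Select exactly the posts with at least one alias match."""
    kept: list[Post] = []
    provenance: dict[str, str] = {}
    for post in posts:
        m = matcher.search(post.body)
        if m:
            kept.append(post)
            provenance[post.post_id] = m.group(0)
    return DrugCorpus(drug_id=drug_id, posts=kept, provenance=provenance)


def merge_corpora(corpora: Sequence[DrugCorpus], class_id: str) -> DrugCorpus:
    """Union of member corpora, deduplicated by post_id.

    A post mentioning several class members appears once, keeping the
    provenance of the first corpus that contributed it.
    """
    if not corpora:
        raise ValueError("at least one corpus is required")
    seen: set[str] = set()
    posts: list[Post] = []
    provenance: dict[str, str] = {}
    for corpus in corpora:
        for post in corpus.posts:
            if post.post_id not in seen:
                seen.add(post.post_id)
                posts.append(post)
                provenance[post.post_id] = corpus.provenance.get(post.post_id, "")
    return DrugCorpus(drug_id=class_id, posts=posts, provenance=provenance)
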