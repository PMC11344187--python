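"""Parsing, serialization and labeling of PTT-style forum threads.

PTT is a Taiwanese terminal BBS. Web-facing threads carry a header
(author 作者, time 時間, title 標題) and follow-up comments, each marked
with one of three reaction characters: 推 (like), 噓 (boo) or → (neutral).
This module defines the in-memory thread model (:class:`Comment`,
:class:`Post`), a documented plain-text dialect for storing threads, the
user-anonymization step, the keyword board filter, and ingestion of the
two-rater stance label table.
"""

from __future__ import annotations

import csv
import io
import logging
import string
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Stance layers of the multilayer network.
LAYERS = ("P", "H", "A")

#: All admissible board labels. ``P``/``H``/``A`` enter the network;
#: ``neutral`` and ``irrelevant`` are excluded from analysis.
LABELS = ("P", "H", "A", "neutral", "irrelevant", "unlabeled")

#: Reaction mark on a comment -> canonical reaction name.
MARK_TO_REACTION = {"推": "like", "噓": "boo", "→": "neutral"}
REACTION_TO_MARK = {v: k for k, v in MARK_TO_REACTION.items()}

#: PTT wraps comment text at this many characters per line.
COMMENT_LINE_WIDTH = 39

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


class EmptyCorpusError(ValueError):
    """Raised when a source yields zero parseable posts."""


class AnonymizationCapacityError(RuntimeError):
    """Raised when distinct users exceed the 36^6 token space."""


@dataclass(frozen=True, slots=True)
class Comment:
    """A single follow-up comment on a post."""

    commenter: str
    reaction: str  # "like" | "boo" | "neutral"
    time: datetime
    text: str = ""

    def __post_init__(self) -> None:
        if self.reaction not in MARK_TO_REACTION.values():
            raise ValueError(f"unknown reaction {self.reaction!r}")


@dataclass(slots=True)
class Post:
    """One board/thread: header fields plus its ordered comments."""

    board_id: str
    author: str
    time: datetime
    title: str
    label: str = "unlabeled"
    comments: list[Comment] = field(default_factory=list)
    ip: str = "0.0.0.0"  # placeholder; real addresses are never modeled

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class LabelTable:
    """Two-rater stance labels per board, plus the resolved final label."""

    rows: dict[str, tuple[str, str, str]]  # board_id -> (rater1, rater2, final)

    def __post_init__(self) -> None:
        for board_id, (r1, r2, final) in self.rows.items():
            if not final:
                raise ValueError(f"board {board_id} has no final label")
            if r1 == r2 and final != r1:
                raise ValueError(
                    f"board {board_id}: raters agree on {r1!r} but final is {final!r}"
                )

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_csv(cls, path) -> "LabelTable":
        rows: dict[str, tuple[str, str, str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                rows[rec["board_id"]] = (rec["rater1"], rec["rater2"], rec["final"])
        return cls(rows)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["board_id", "rater1", "rater2", "final"])
            for board_id, (r1, r2, final) in self.rows.items():
                writer.writerow([board_id, r1, r2, final])


# ---------------------------------------------------------------------------
# Thread-text dialect
#
# One record per post:
#
#     === POST <board_id> ===
#     作者: <author>
#     時間: <ISO-8601 time>
#     標題: <title>
#     標籤: <label>            (omitted when unlabeled)
#     ----
#     <MARK>\t<user>\t<ISO time>\t<text, first 39 chars>
#     \t\t\t<text continuation, 39-char chunks>
#     === END ===
#
# Comment text longer than 39 characters is wrapped onto continuation
# lines (empty mark/user/time fields); the parser re-joins the chunks.
# ---------------------------------------------------------------------------


_SANITIZE = str.maketrans({"\t": " ", "\n": " ", "\r": " "})


def _clean(text: str) -> str:
    # tabs/newlines are the dialect's separators; mapped to spaces on emit
    return text.translate(_SANITIZE)


def _wrap(text: str) -> list[str]:
    if not text:
        return [""]
    return [text[i : i + COMMENT_LINE_WIDTH] for i in range(0, len(text), COMMENT_LINE_WIDTH)]


def format_post(post: Post) -> str:
    """Serialize one post in the thread-text dialect."""
    lines = [
        f"=== POST {_clean(post.board_id)} ===",
        f"作者: {_clean(post.author)}",
        f"時間: {post.time.strftime(_TIME_FMT)}",
        f"標題: {_clean(post.title)}",
    ]
    if post.label != "unlabeled":
        lines.append(f"標籤: {post.label}")
    lines.append("----")
    for c in post.comments:
        chunks = _wrap(_clean(c.text))
        mark = REACTION_TO_MARK[c.reaction]
        lines.append(f"{mark}\t{_clean(c.commenter)}\t{c.time.strftime(_TIME_FMT)}\t{chunks[0]}")
        for chunk in chunks[1:]:
            lines.append(f"\t\t\t{chunk}")
    lines.append("=== END ===")
    return "\n".join(lines) + "\n"


def _iter_sources(source):
    """Yield line iterators from a path (file or directory) or file-like."""
    if hasattr(source, "read"):
        yield iter(source)
        return
    path = Path(source)
    if path.is_dir():
        files = sorted(path.glob("*.txt"))
        if not files:
            raise EmptyCorpusError(f"no .txt thread files under {path}")
        for f in files:
            with open(f, encoding="utf-8") as fh:
                yield iter(fh)
    else:
        with open(path, encoding="utf-8") as fh:
            yield iter(fh)


def parse_threads(source) -> list[Post]:
    """Parse thread-text into :class:`Post` objects.

    ``source`` may be a single file path, a directory of ``.txt`` files,
    or an open text stream. Malformed comment lines and truncated
    records are skipped with a logged warning and counted; a source with
    zero parseable posts raises :class:`EmptyCorpusError`.
    """
    posts: list[Post] = []
    n_malformed = 0
    for lines in _iter_sources(source):
        post: Post | None = None
        for raw in lines:
            line = raw.rstrip("\n")
            if line.startswith("=== POST "):
                post = Post(
                    board_id=line[len("=== POST ") : -len(" ===")].strip(),
                    author="",
                    time=datetime.min,
                    title="",
                )
                continue
            if post is None:
                if line.strip():
                    n_malformed += 1
                continue
            if line == "=== END ===":
                if post.author and post.time != datetime.min:
                    posts.append(post)
                else:
                    n_malformed += 1
                    logger.warning("skipping truncated record %s", post.board_id)
                post = None
            elif line.startswith("作者: "):
                post.author = line[len("作者: ") :]
            elif line.startswith("時間: "):
                post.time = datetime.strptime(line[len("時間: ") :], _TIME_FMT)
            elif line.startswith("標題: "):
                post.title = line[len("標題: ") :]
            elif line.startswith("標籤: "):
                post.label = line[len("標籤: ") :]
            elif line == "----":
                continue
            elif line.startswith("\t\t\t"):
                if post.comments:
                    last = post.comments[-1]
                    post.comments[-1] = replace(last, text=last.text + line[3:])
                else:
                    n_malformed += 1
            else:
                parts = line.split("\t")
                if len(parts) != 4 or parts[0] not in MARK_TO_REACTION:
                    n_malformed += 1
                    logger.warning("malformed comment line skipped: %r", line[:60])
                    continue
                mark, user, time_str, text = parts
                try:
                    ctime = datetime.strptime(time_str, _TIME_FMT)
                except ValueError:
                    n_malformed += 1
                    continue
                post.comments.append(
                    Comment(commenter=user, reaction=MARK_TO_REACTION[mark], time=ctime, text=text)
                )
    if n_malformed:
        logger.warning("skipped %d malformed lines/records", n_malformed)
    if not posts:
        raise EmptyCorpusError("source contained zero parseable posts")
    return posts


_TOKEN_ALPHABET = string.ascii_uppercase + string.digits  # 36 symbols


def anonymize(posts: list[Post], seed: int) -> tuple[list[Post], dict[str, str]]:
    """Replace raw usernames with 6-character alphanumeric tokens.

    The mapping is injective and deterministic given ``seed``. Returns
    new posts (raw names absent) and the raw->token map, which callers
    keep out of published outputs.
    """
    users = sorted(
        {p.author for p in posts} | {c.commenter for p in posts for c in p.comments}
    )
    if len(users) > 36**6:
        raise AnonymizationCapacityError("more distinct users than 6-char tokens")
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for user in users:
        while True:
            token = "".join(_TOKEN_ALPHABET[i] for i in rng.integers(0, 36, size=6))
            if token not in used:
                break
        used.add(token)
        mapping[user] = token
    out = []
    for p in posts:
        out.append(
            Post(
                board_id=p.board_id,
                author=mapping[p.author],
                time=p.time,
                title=p.title,
                label=p.label,
                comments=[replace(c, commenter=mapping[c.commenter]) for c in p.comments],
                ip=p.ip,
            )
        )
    return out, mapping


def filter_vaccine_boards(posts: list[Post], keyword: str = "疫苗") -> list[Post]:
    """Retain posts whose title or any comment text contains ``keyword``.

    Matching is plain substring, case-insensitive for Latin text. Both
    the title and the comment bodies are searched.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    key = keyword.casefold()
    kept = [
        p
        for p in posts
        if key in p.title.casefold() or any(key in c.text.casefold() for c in p.comments)
    ]
    logger.info("keyword filter %r: retained %d, dropped %d", keyword, len(kept), len(posts) - len(kept))
    return kept


def interrater_agreement(table: LabelTable) -> tuple[float, list[str]]:
    """Percentage of boards on which the two raters agree.

    Returns ``(percentage, disagreement_board_ids)``; the disagreement
    list is what gets passed on for resolution by a third party.
    """
    if not table.rows:
        raise ValueError("empty label table")
    disagreements = [b for b, (r1, r2, _) in table.rows.items() if r1 != r2]
    pct = 100.0 * (len(table) - len(disagreements)) / len(table)
    return pct, disagreements


def apply_final_labels(posts: list[Post], table: LabelTable) -> list[Post]:
    """Attach final labels and drop neutral/irrelevant boards.

    Boards labeled ``neutral`` or ``irrelevant`` are excluded from the
    analysis set. Every post's board must appear in the table.
    """
    missing = [p.board_id for p in posts if p.board_id not in table.rows]
    if missing:
        raise KeyError(f"boards missing from label table: {missing[:20]}")
    out = []
    for p in posts:
        final = table.rows[p.board_id][2]
        if final in ("neutral", "irrelevant"):
            continue
        if final not in LAYERS:
            raise ValueError(f"board {p.board_id}: unknown final label {final!r}")
        out.append(replace_label(p, final))
    logger.info("labels applied: %d retained, %d excluded", len(out), len(posts) - len(out))
    return out


def replace_label(post: Post, label: str) -> Post:
    return Post(
        board_id=post.board_id,
        author=post.author,
        time=post.time,
        title=post.title,
        label=label,
        comments=list(post.comments),
        ip=post.ip,
    )


def posts_to_text(posts: list[Post]) -> str:
    """Serialize a corpus to a single thread-text string."""
    buf = io.StringIO()
    for p in posts:
        buf.write(format_post(p))
        buf.write("\n")
    return buf.getvalue()
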