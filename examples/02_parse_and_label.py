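"""Parse thread text, anonymize users, and apply two-rater board labels.

Thread text uses the documented dialect (header block + one tab-separated
line per comment with its 推/噓/→ reaction mark). Usernames are replaced
by 6-character alphanumeric tokens before any analysis output.
"""

import io

from stancenet import LabelTable, anonymize, interrater_agreement, parse_threads, apply_final_labels

THREADS = """\
=== POST B001 ===
作者: wang_123
時間: 2021-03-01T10:00:00
標題: 打完疫苗心得
----
推\tchen_456\t2021-03-01T10:05:00\t恭喜
噓\tlin_789\t2021-03-01T10:06:00\t不信
→\twu_000\t2021-03-01T10:07:00\t看看再說
=== END ===

=== POST B002 ===
作者: lin_789
時間: 2021-03-02T09:00:00
標題: 疫苗副作用太多了
----
推\twu_000\t2021-03-02T09:10:00\t同意
=== END ===
"""

posts = parse_threads(io.StringIO(THREADS))
posts, mapping = anonymize(posts, seed=11)
print(f"parsed {len(posts)} posts; users anonymized, e.g. wang_123 -> {mapping['wang_123']}")

# two raters labeled each board; final label resolves disagreements
table = LabelTable({"B001": ("P", "P", "P"), "B002": ("H", "A", "H")})
pct, disagreements = interrater_agreement(table)
print(f"interrater agreement: {pct:.0f}% (disagreements: {disagreements})")

labeled = apply_final_labels(posts, table)
print(f"analysis set: {[(p.board_id, p.label) for p in labeled]}")
# neutral/irrelevant boards would be dropped here; both boards are stance-labeled
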