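"""Praat TextGrid reading/writing for word + phoneme alignments.

Supports the long "ooTextFile" TextGrid format with two interval tiers named
``words`` and ``phones`` (the layout forced aligners emit). Phonemes are
attached to the word whose interval contains their midpoint; intervals whose
label is a silence marker become silence.
"""

from __future__ import annotations

import bisect
import re
from pathlib import Path

from .features import SILENCE_LABELS, Alignment, PhonemeInterval, WordInterval


def write_textgrid(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as a two-tier (words, phones) long-format TextGrid.

    Gaps between units are filled with empty-label (silence) intervals so the
    tiers tile [0, xmax] as Praat requires.
    """
    xmax = alignment.end_time
    tiers = {
        "words": [(w.label, w.start, w.end) for w in alignment.words],
        "phones": [(p.label, p.start, p.end) for p in alignment.phonemes],
    }
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 2",
        "item []:",
    ]
    for ti, (name, intervals) in enumerate(tiers.items(), start=1):
        filled: list[tuple[str, float, float]] = []
        cursor = 0.0
        for label, start, end in intervals:
            if start > cursor + 1e-9:
                filled.append(("", cursor, start))
            filled.append((label, start, end))
            cursor = end
        if xmax > cursor + 1e-9:
            filled.append(("", cursor, xmax))
        if not filled:
            filled = [("", 0.0, max(xmax, 1e-6))]
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(filled)}",
        ]
        for ii, (label, start, end) in enumerate(filled, start=1):
            lines += [
                f"        intervals [{ii}]:",
                f"            xmin = {start:.6f}",
                f"            xmax = {end:.6f}",
                f'            text = "{label}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n")


_ITEM_RE = re.compile(r"item \[\d+\]:")
_KV_RE = re.compile(r"^\s*([a-zA-Z?\[\]: ]+?)\s*=\s*(.*)$")


def _parse_tiers(text: str) -> dict[str, list[tuple[str, float, float]]]:
    tiers: dict[str, list[tuple[str, float, float]]] = {}
    name = None
    cur: dict[str, str] = {}
    intervals: list[tuple[str, float, float]] = []

    def flush_interval() -> None:
        if {"xmin", "xmax", "text"} <= cur.keys():
            intervals.append(
                (cur["text"].strip('"'), float(cur["xmin"]), float(cur["xmax"]))
            )
        cur.clear()

    for raw in text.splitlines():
        line = raw.strip()
        if _ITEM_RE.fullmatch(line) and name is not None:
            flush_interval()
            tiers[name] = intervals
            name, intervals = None, []
        if line.startswith("intervals ["):
            flush_interval()
            continue
        m = _KV_RE.match(line)
        if not m:
            continue
        key, value = m.group(1).strip(), m.group(2).strip()
        if key == "name":
            name = value.strip('"')
        elif key in {"xmin", "xmax", "text"}:
            cur[key] = value
    flush_interval()
    if name is not None:
        tiers[name] = intervals
    return tiers


def read_textgrid(
    path: str | Path,
    silence_labels: frozenset[str] | set[str] = SILENCE_LABELS,
    validate: bool = True,
) -> Alignment:
    """Parse a long-format TextGrid with ``words`` and ``phones`` tiers."""
    tiers = _parse_tiers(Path(path).read_text())
    missing = {"words", "phones"} - tiers.keys()
    if missing:
        raise ValueError(f"TextGrid lacks tier(s): {sorted(missing)}")

    words = [
        WordInterval(label, start, end)
        for label, start, end in tiers["words"]
        if label not in silence_labels
    ]
    word_starts = [w.start for w in words]
    phonemes = []
    for label, start, end in tiers["phones"]:
        if label in silence_labels:
            continue
        mid = 0.5 * (start + end)
        i = bisect.bisect_right(word_starts, mid + 1e-9) - 1
        word_index = (
            i if 0 <= i < len(words) and mid <= words[i].end + 1e-9 else None
        )
        phonemes.append(PhonemeInterval(label, start, end, word_index))
    return Alignment(words=words, phonemes=phonemes, validate=validate)
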