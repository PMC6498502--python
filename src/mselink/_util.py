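"""Small shared helpers."""

from __future__ import annotations

import math
import re
import unicodedata


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the convention used for all reported counts and percentages
    (``round`` in Python rounds halves to even, which does not reproduce
    printed percentages such as 50.5% -> 51%).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


_PUNCT_RE = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical form of a personal name used as the linkage key.

    Case-folds, strips diacritics (NFKD, combining marks removed), replaces
    punctuation with spaces and collapses runs of whitespace. Benign
    rendering differences between lists (capitalisation, stray periods,
    doubled spaces) therefore normalise to the same key.
    """
    s = unicodedata.normalize("NFKD", name)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.casefold()
    s = _PUNCT_RE.sub(" ", s)
    s = _WS_RE.sub(" ", s).strip()
    return s


def edit_distance_at_most(a: str, b: str, k: int) -> bool:
    """True if Levenshtein distance between *a* and *b* is <= *k*.

    Banded dynamic program; only used when fuzzy name matching is enabled.
    """
    if abs(len(a) - len(b)) > k:
        return False
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        best = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            best = min(best, cur[j])
        if best > k:
            return False
        prev = cur
    return prev[-1] <= k
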