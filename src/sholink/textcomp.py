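"""String comparators for identifier fields.

Administrative identifier fields are short ASCII-like tokens, so the
classic linkage comparators -- Levenshtein edit distance, Jaro-Winkler
similarity, and American Soundex -- are implemented directly here.
All comparators operate on canonicalized strings; canonicalization
case-folds, strips diacritics, and removes everything that is not a
letter (hyphens, apostrophes, internal spaces).
"""

from __future__ import annotations

import unicodedata
from functools import lru_cache

__all__ = ["canonicalize_name", "levenshtein", "damerau_osa", "jaro", "jaro_winkler", "soundex"]


@lru_cache(maxsize=65536)
def canonicalize_name(name: str | None) -> str:
    """Case-fold, strip diacritics, and drop non-letter characters.

    ``O'Brien`` -> ``obrien``; ``Mary-Jane`` -> ``maryjane``; ``José`` -> ``jose``.
    Returns the empty string for ``None`` or whitespace-only input.
    """
    if not name:
        return ""
    decomposed = unicodedata.normalize("NFKD", name)
    return "".join(c for c in decomposed.casefold() if c.isascii() and c.isalpha())


def levenshtein(a: str, b: str) -> int:
    """Edit distance with unit substitution/insertion/deletion costs."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, 1):
            append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def damerau_osa(a: str, b: str) -> int:
    """Optimal-string-alignment distance: Levenshtein plus unit-cost
    transposition of adjacent characters.

    This is the natural typo distance when keystroke errors include
    swapped neighbours: ``"smiht" -> "smith"`` costs 1, not 2.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    la, lb = len(a), len(b)
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = a[i - 1] != b[j - 1]
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                prev2 is not None
                and i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def jaro(a: str, b: str) -> float:
    """Jaro similarity in [0, 1]."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    matched_b = [False] * lb
    matches_a = []
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not matched_b[j] and b[j] == ca:
                matched_b[j] = True
                matches_a.append(ca)
                break
    m = len(matches_a)
    if m == 0:
        return 0.0
    matches_b = [b[j] for j in range(lb) if matched_b[j]]
    transpositions = sum(x != y for x, y in zip(matches_a, matches_b)) // 2
    return (m / la + m / lb + (m - transpositions) / m) / 3.0


def jaro_winkler(a: str, b: str, prefix_scale: float = 0.1, boost_threshold: float = 0.7) -> float:
    """Jaro-Winkler similarity: Jaro with a bonus for a shared prefix (<= 4 chars)."""
    j = jaro(a, b)
    if j <= boost_threshold:
        return j
    prefix = 0
    for ca, cb in zip(a[:4], b[:4]):
        if ca != cb:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)


_SOUNDEX_CODES = {}
for _letters, _digit in (
    ("bfpv", "1"),
    ("cgjkqsxz", "2"),
    ("dt", "3"),
    ("l", "4"),
    ("mn", "5"),
    ("r", "6"),
):
    for _c in _letters:
        _SOUNDEX_CODES[_c] = _digit


@lru_cache(maxsize=65536)
def soundex(name: str) -> str:
    """American Soundex code (letter + 3 digits), computed on the canonical form.

    ``h``/``w`` are transparent (consonants with the same code on either side
    collapse); vowels separate codes. Empty canonical input yields "".
    """
    s = canonicalize_name(name)
    if not s:
        return ""
    out = [s[0].upper()]
    prev_code = _SOUNDEX_CODES.get(s[0], "")
    for c in s[1:]:
        code = _SOUNDEX_CODES.get(c, "")
        if c in "hw":
            continue  # transparent: keep prev_code
        if code and code != prev_code:
            out.append(code)
            if len(out) == 4:
                break
        prev_code = code
    return "".join(out).ljust(4, "0")
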