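"""Independent reference implementations used only to check the package.

These deliberately re-derive results through different code paths than the
implementation: a top-down memoized lexicographic DP, a full recursive
enumeration of alignments for tiny inputs, and a prefix-counting majority
resolver for taxonomy tie-breaking.
"""

from functools import lru_cache

MATCH, MISMATCH, GAP = 1, -1, -2


def lex_align_oracle(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, -mismatches), lexicographically maximal, top-down."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> tuple[int, int, int]:
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        cands = []
        if i < len(a) and j < len(b):
            s, m, nx = go(i + 1, j + 1)
            if a[i] == b[j]:
                cands.append((s + MATCH, m + 1, nx))
            else:
                cands.append((s + MISMATCH, m, nx - 1))
        if i < len(a):
            s, m, nx = go(i + 1, j)
            cands.append((s + GAP, m, nx))
        if j < len(b):
            s, m, nx = go(i, j + 1)
            cands.append((s + GAP, m, nx))
        return max(cands)

    result = go(0, 0)
    go.cache_clear()
    return result


def enumerate_align_oracle(a: str, b: str) -> tuple[int, int, int]:
    """Exhaustive enumeration of every global alignment (tiny inputs only)."""
    best: list[tuple[int, int, int] | None] = [None]

    def walk(i: int, j: int, score: int, matches: int, mismatches: int) -> None:
        if i == len(a) and j == len(b):
            cand = (score, matches, -mismatches)
            if best[0] is None or cand > best[0]:
                best[0] = cand
            return
        if i < len(a) and j < len(b):
            if a[i] == b[j]:
                walk(i + 1, j + 1, score + MATCH, matches + 1, mismatches)
            else:
                walk(i + 1, j + 1, score + MISMATCH, matches, mismatches + 1)
        if i < len(a):
            walk(i + 1, j, score + GAP, matches, mismatches)
        if j < len(b):
            walk(i, j + 1, score + GAP, matches, mismatches)

    walk(0, 0, 0, 0, 0)
    assert best[0] is not None
    return best[0]


def similarity_oracle(a: str, b: str) -> float | None:
    s, m, nx = lex_align_oracle(a, b)
    x = -nx
    return None if m + x == 0 else 100.0 * m / (m + x)


def majority_prefix_oracle(paths: list[tuple[tuple[str, str], ...]]) -> tuple[tuple[str, str], ...]:
    """Longest path prefix shared by a strict majority, by prefix counting."""
    k = len(paths)
    best: tuple[tuple[str, str], ...] = ()
    for path in paths:
        for plen in range(1, len(path) + 1):
            prefix = path[:plen]
            support = sum(1 for other in paths if other[:plen] == prefix)
            if 2 * support > k and plen > len(best):
                best = prefix
    return best
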