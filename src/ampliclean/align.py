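"""Global pairwise alignment and the gap-excluded percent similarity.

The similarity measure used throughout the analysis stages counts, on an
optimal global alignment of two sequences, the identical aligned base pairs
as a fraction of the aligned columns in which *neither* sequence has a gap.
Gap columns are excluded entirely, so two sequences that differ only by
insertions/deletions score 100%.

Scoring is linear: match +1, mismatch -1, gap -2. Because co-optimal
alignments under a linear scheme can trade a mismatch against gap columns
(changing the similarity while preserving the score), the alignment is made
canonical by lexicographic optimisation: maximise score, then the number of
matched columns, then minimise mismatched columns (i.e. prefer gaps over
mismatches at equal score). The three additive objectives are folded into a
single 64-bit integer DP with non-interfering weights, so the optimum can be
decoded from the final cell without traceback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MATCH = 1
MISMATCH = -1
GAP = -2


@dataclass(frozen=True)
class AlignmentStats:
    """Column tallies of the canonical optimal global alignment."""

    score: int
    matches: int
    mismatches: int

    @property
    def gap_free_columns(self) -> int:
        return self.matches + self.mismatches

    @property
    def similarity(self) -> float | None:
        """Percent identity over gap-free columns; None if no such column."""
        n = self.gap_free_columns
        if n == 0:
            return None
        return 100.0 * self.matches / n


def align_stats(a: str, b: str) -> AlignmentStats:
    """Align ``a`` against ``b`` globally and return column statistics."""
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return AlignmentStats(GAP * (la + lb), 0, 0)

    # Weight layout: value = score*W1 + matches*W2 - mismatches. W2 exceeds
    # the mismatch range and W1 exceeds the whole lower-order range, so a
    # plain max-DP on the packed value realises the lexicographic optimum.
    big = la + lb
    w2 = big + 1
    w1 = big * w2 + big + 1
    diag_match = MATCH * w1 + w2
    diag_mismatch = MISMATCH * w1 - 1
    gap_w = GAP * w1

    b_codes = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    j_idx = np.arange(lb + 1, dtype=np.int64)
    jg = j_idx * (-gap_w)  # helper for the running-max left-gap recurrence

    prev = j_idx * gap_w
    t = np.empty(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        sub = np.where(b_codes == ord(a[i - 1]), diag_match, diag_mismatch)
        t[0] = i * gap_w
        np.maximum(prev[:-1] + sub, prev[1:] + gap_w, out=t[1:])
        # cur[j] = max_{k<=j} t[k] + gap_w*(j-k), computed via prefix max
        prev = np.maximum.accumulate(t + jg) - jg

    packed = int(prev[lb])
    shifted = packed + 2 * big * w1 + big
    score = shifted // w1 - 2 * big
    rest = shifted % w1
    matches = rest // w2
    mismatches = big - rest % w2
    return AlignmentStats(int(score), int(matches), int(mismatches))


def similarity(a: str, b: str) -> float | None:
    """Gap-excluded percent similarity of two sequences (None = no overlap)."""
    return align_stats(a, b).similarity
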