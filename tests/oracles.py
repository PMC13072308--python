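"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results through a different route than the
package (plain quadratic dynamic programming, direct set counting) so that
agreement is evidence, not tautology. Nothing here imports phagekit's
implementation internals.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def sw_score_oracle(
    seq_a: str, seq_b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Smith-Waterman local alignment score by explicit Gotoh recursion.

    Affine gaps in the BLAST convention: a gap of length L costs
    ``gap_open + L * gap_extend``. Quadratic time and memory, pure Python.
    """
    n, m = len(seq_a), len(seq_b)
    first_gap = gap_open + gap_extend  # cost of the first residue of a gap
    best = 0.0
    h_prev = [0.0] * (m + 1)
    f_prev = [NEG_INF] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        f_cur = [NEG_INF] * (m + 1)
        e = NEG_INF  # gap in seq_a, consuming seq_b
        row_a = seq_a[i - 1]
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - first_gap, e - gap_extend)
            f_cur[j] = max(h_prev[j] - first_gap, f_prev[j] - gap_extend)
            diag = h_prev[j - 1] + _BLOSUM62[row_a, seq_b[j - 1]]
            h = max(0.0, diag, e, f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_cur, f_cur
    return best


def membership_consensus_oracle(
    keysets: dict[str, frozenset], k: int
) -> frozenset:
    """Keys present in at least k of the given per-tool key sets."""
    union = set().union(*keysets.values())
    return frozenset(
        key for key in union if sum(key in s for s in keysets.values()) >= k
    )


def brute_force_regions(keysets: dict[str, frozenset]) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts by enumerating all 2^N - 1 subsets."""
    tools = sorted(keysets)
    union = set().union(*keysets.values())
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(tools) + 1):
        for combo in combinations(tools, r):
            inside = set(combo)
            region = [
                key
                for key in union
                if all(key in keysets[t] for t in inside)
                and not any(key in keysets[t] for t in set(tools) - inside)
            ]
            counts[tuple(combo)] = len(region)
    return counts
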