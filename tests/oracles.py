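"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementations: each is a direct,
unoptimized transcription of the rule being checked.
"""

from __future__ import annotations


def union_runs_oracle(sig: list[bool]) -> list[tuple[int, int]]:
    """Literal traversal of the window rule, in oligo-index units.

    Traverse 5'->3'; open a window at an enriched oligo and extend it while
    oligos stay enriched. At the first non-enriched oligo x, let y be the
    distance to the next enriched oligo. If every oligo in [x+y, x+2y) is
    enriched, the window extends to x+2y-1 and the process continues there;
    otherwise the window closes at its last enriched member.
    """
    n = len(sig)
    windows: list[tuple[int, int]] = []
    pos = 0
    while pos < n:
        if not sig[pos]:
            pos += 1
            continue
        start = pos
        cur = pos
        while True:
            while cur + 1 < n and sig[cur + 1]:
                cur += 1
            x = cur + 1
            if x >= n:
                break
            nexts = [j for j in range(x, n) if sig[j]]
            if not nexts:
                break
            y = nexts[0] - x
            bridge = list(range(x + y, x + 2 * y))
            if bridge[-1] < n and all(sig[j] for j in bridge):
                cur = x + 2 * y - 1
            else:
                break
        windows.append((start, cur))
        pos = cur + 1
    return windows


def max_ag_window_oracle(seq: str, window: int) -> tuple[float, int]:
    """O(n*w) scan over every window; ties resolve to the 5'-most start."""
    seq = seq.upper().replace("U", "T")
    best_frac, best_start = -1.0, 0
    for start in range(len(seq) - window + 1):
        sub = seq[start : start + window]
        frac = sum(1 for b in sub if b in "AG") / window
        if frac > best_frac:
            best_frac, best_start = frac, start
    return best_frac, best_start


def count_deletions_oracle(read: str, template: str) -> int:
    """Number of template bases skipped within a mutation-free read.

    Greedy: any mismatch must be a deletion (the read was generated with zero
    substitution rate), so advance the template cursor until bases realign.
    """
    deletions = 0
    t = 0
    for base in read:
        if base == "N":
            break  # template exhausted during simulation
        while template[t] != base:
            deletions += 1
            t += 1
        t += 1
    return deletions


def interval_union_span(intervals: list[tuple[int, int]]) -> tuple[int, int]:
    """Genomic span of a set of half-open intervals."""
    return min(s for s, _ in intervals), max(e for _, e in intervals)
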