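"""Active-window calling: contiguous runs of neurite-enriched oligos.

A *union* is opened at the first significant oligo encountered while
traversing a gene's tiling 5'->3' and extended oligo by oligo. When a
non-significant oligo is reached, its index is ``x``; the distance (in oligo
indices) to the next significant oligo is ``y``. If every oligo in
``[x + y, x + 2y)`` is significant, the window is extended through
``x + 2y - 1`` — the bridged gap oligos stay in the window as members — and
traversal resumes at ``x + 2y`` with the same rule applied afresh. Otherwise
the window closes at its last significant member. A window whose bridge test
would run past the end of the tiling closes at the last significant member.

``x``/``y`` are measured in oligo-index units; with a uniform step this is
proportional to nucleotide distance and stays well defined at the anchored
final oligo.

The *intersection* of a union is the subsequence shared by all of its member
oligos: ``[last_offset, first_offset + oligo_length)``, empty when the member
starts span at least one oligo length. The *peak* oligo is the most enriched
significant member, ties broken toward the union midpoint, then 5'-most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .enrich import EnrichmentRecord

DEFAULT_FDR_CUTOFF = 0.01
DEFAULT_OLIGO_LENGTH = 260


class WindowError(ValueError):
    pass


@dataclass
class ActiveWindow:
    gene_id: str
    member_oligos: list[str]
    member_offsets: list[int]
    oligo_length: int = DEFAULT_OLIGO_LENGTH
    peak_oligo_id: str | None = None

    @property
    def first_offset(self) -> int:
        return self.member_offsets[0]

    @property
    def last_offset(self) -> int:
        return self.member_offsets[-1]

    @property
    def union_interval(self) -> tuple[int, int]:
        return self.first_offset, self.last_offset + self.oligo_length

    @property
    def intersection_interval(self) -> tuple[int, int] | None:
        lo, hi = self.last_offset, self.first_offset + self.oligo_length
        return (lo, hi) if lo < hi else None


def _is_enriched(rec: EnrichmentRecord, fdr_cutoff: float, direction: str) -> bool:
    if not np.isfinite(rec.fdr) or rec.fdr >= fdr_cutoff:
        return False
    return rec.log2fc > 0 if direction == "neurite" else rec.log2fc < 0


def _validate_tiling(records: Sequence[EnrichmentRecord]) -> None:
    offsets = [r.offset for r in records]
    if any(o is None for o in offsets):
        raise WindowError("records must carry offsets (join with the pool manifest)")
    diffs = np.diff(offsets)
    if len(diffs) and np.any(diffs <= 0):
        raise WindowError("records must be strictly increasing in offset")
    if len(diffs) > 1:
        step = int(diffs[0])
        # uniform step; the final anchored oligo may sit closer than step
        if np.any(diffs[:-1] != step) or diffs[-1] > step:
            raise WindowError("gapped or non-uniform tiling; complete tiling required")


def call_unions(
    records: Sequence[EnrichmentRecord],
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    oligo_length: int = DEFAULT_OLIGO_LENGTH,
    direction: str = "neurite",
    gene_id: str | None = None,
) -> list[ActiveWindow]:
    """Call oligo unions for one gene's complete, offset-ordered tiling.

    Significance is ``fdr < fdr_cutoff`` and the direction-appropriate sign of
    ``log2fc``. Returns windows in 5'->3' order with peaks assigned.
    """
    if not records:
        return []
    _validate_tiling(records)
    sig = [_is_enriched(r, fdr_cutoff, direction) for r in records]
    runs = _call_union_index_runs(sig)
    windows = []
    for start, end in runs:  # inclusive index range
        members = records[start : end + 1]
        win = ActiveWindow(
            gene_id=gene_id or "",
            member_oligos=[r.oligo_id for r in members],
            member_offsets=[int(r.offset) for r in members],
            oligo_length=oligo_length,
        )
        win.peak_oligo_id = pick_peak(win, members, fdr_cutoff, direction)
        windows.append(win)
    return windows


def _call_union_index_runs(sig: Sequence[bool]) -> list[tuple[int, int]]:
    """Union calling on a plain significance vector; returns inclusive index
    ranges ``(first_member, last_member)``."""
    n = len(sig)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        start = i
        last_sig = i
        i += 1
        while i < n:
            if sig[i]:
                last_sig = i
                i += 1
                continue
            x = i  # first non-enriched oligo after the run
            nxt = next((j for j in range(x + 1, n) if sig[j]), None)
            if nxt is None:
                break  # no further enriched oligo: close at last member
            y = nxt - x
            bridge = list(range(x + y, x + 2 * y))
            if bridge and bridge[-1] < n and all(sig[j] for j in bridge):
                last_sig = x + 2 * y - 1
                i = x + 2 * y  # resume with a fresh x/y
            else:
                break  # bridge fails (or would run past the end): close
        runs.append((start, last_sig))
        i = max(i, last_sig + 1)
    return runs


def derive_intersection(window: ActiveWindow) -> tuple[int, int] | None:
    """Interval common to every member oligo, or ``None`` when empty."""
    return window.intersection_interval


def pick_peak(
    window: ActiveWindow,
    records: Sequence[EnrichmentRecord],
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    direction: str = "neurite",
) -> str:
    """Most enriched significant member; ties broken by proximity to the union
    midpoint, then 5'-most."""
    if not records:
        raise WindowError("empty window")
    sig = [r for r in records if _is_enriched(r, fdr_cutoff, direction)]
    pool = sig or list(records)
    lo, hi = window.union_interval
    mid = (lo + hi) / 2.0

    def magnitude(r: EnrichmentRecord) -> float:
        return r.log2fc if direction == "neurite" else -r.log2fc

    best = max(
        pool,
        key=lambda r: (
            magnitude(r),
            -abs(r.offset + window.oligo_length / 2.0 - mid),
            -r.offset,
        ),
    )
    return best.oligo_id


def neighbor_similarity_test(
    records: Sequence[EnrichmentRecord],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Neighbor-difference QC: are adjacent oligos more similar than chance?

    Observed statistic: ``|log2fc_i - log2fc_{i+1}|`` over adjacent pairs.
    The positional relationship is destroyed by permuting offsets within the
    gene ``n_shuffles`` times; a two-sided Wilcoxon rank-sum test compares the
    observed differences with the pooled shuffled differences.

    Returns ``(observed, shuffled, pvalue)``.
    """
    if len(records) < 3:
        raise WindowError("need >= 3 oligos for the neighbor-similarity test")
    values = np.array([r.log2fc for r in records], dtype=float)
    observed = np.abs(np.diff(values))
    rng = np.random.default_rng(seed)
    shuffled = np.concatenate(
        [np.abs(np.diff(rng.permutation(values))) for _ in range(n_shuffles)]
    )
    if np.ptp(values) == 0:
        return observed, shuffled, 1.0  # constant profile: nothing to test
    stat = stats.ranksums(observed, shuffled)
    return observed, shuffled, float(stat.pvalue)


def smooth_profile(
    records: Sequence[EnrichmentRecord], k: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding mean and sd of log2fc over windows of ``k`` oligos.

    Windows are centered — indices ``[i - (k-1)//2, i + k//2]`` — and shrink
    at the edges. ``k=1`` is the identity.
    """
    if k < 1:
        raise WindowError("k must be >= 1")
    values = np.array([r.log2fc for r in records], dtype=float)
    n = len(values)
    means = np.empty(n)
    sds = np.empty(n)
    for i in range(n):
        lo = max(0, i - (k - 1) // 2)
        hi = min(n, i + k // 2 + 1)
        w = values[lo:hi]
        means[i] = w.mean()
        sds[i] = w.std(ddof=0)
    return means, sds


def windows_to_bed(
    windows: Sequence[ActiveWindow],
    records_by_id: dict[str, EnrichmentRecord] | None = None,
) -> str:
    """BED6 text for called windows (UTR coordinates, score = peak log2fc)."""
    lines = []
    for i, w in enumerate(windows):
        lo, hi = w.union_interval
        score = 0.0
        if records_by_id and w.peak_oligo_id in records_by_id:
            score = records_by_id[w.peak_oligo_id].log2fc
        lines.append(
            f"{w.gene_id}\t{lo}\t{hi}\t{w.gene_id}:union{i + 1}\t{score:.4f}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
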