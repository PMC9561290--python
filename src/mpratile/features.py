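"""Sequence-level characterization: composition, A/G windows, kmers, folding.

U and T are treated as equivalent; sequences are normalized to the DNA
alphabet on input. Ambiguous bases are excluded from composition denominators
and break kmers.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import normalize_alphabet

DEFAULT_AG_WINDOW = 100
DEFAULT_AG_THRESHOLD = 0.75
FOLD_WINDOW = 80
FOLD_STEP = 5

#: Fallback G-quadruplex pattern: four runs of >=3 G separated by 1-7 nt loops.
QUADRUPLEX_RE = re.compile(r"(?:G{3,}[ACGTN]{1,7}){3}G{3,}")


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


@dataclass
class CompositionRecord:
    sequence_id: str
    fraction_a: float
    fraction_c: float
    fraction_g: float
    fraction_t: float

    @property
    def fraction_ag(self) -> float:
        return self.fraction_a + self.fraction_g


def composition(sequences: Iterable[tuple[str, str]]) -> list[CompositionRecord]:
    """Per-base fractions over unambiguous bases for each ``(id, seq)``."""
    out = []
    for sid, raw in sequences:
        seq = normalize_alphabet(raw)
        counts = {b: seq.count(b) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            raise FeatureError(f"sequence {sid!r} has no unambiguous bases")
        out.append(
            CompositionRecord(
                sid,
                counts["A"] / total,
                counts["C"] / total,
                counts["G"] / total,
                counts["T"] / total,
            )
        )
    return out


def compare_composition(
    groups: Mapping[str, Sequence[CompositionRecord]], base: str = "ag"
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of a composition fraction between groups."""
    attr = {"a": "fraction_a", "c": "fraction_c", "g": "fraction_g",
            "t": "fraction_t", "ag": "fraction_ag"}[base]
    names = list(groups)
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            xi = [getattr(r, attr) for r in groups[gi]]
            xj = [getattr(r, attr) for r in groups[gj]]
            res = stats.ranksums(xi, xj)
            rows.append(
                {"group1": gi, "group2": gj, "statistic": res.statistic,
                 "pvalue": res.pvalue}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# A/G-rich windows
# ---------------------------------------------------------------------------


@dataclass
class AGWindowResult:
    sequence_id: str
    window_length: int
    max_ag_fraction: float
    max_window_start: int
    whole_sequence: bool = False  # sequence shorter than the window

    def passes(self, threshold: float = DEFAULT_AG_THRESHOLD) -> bool:
        """Inclusive threshold: a window of exactly ``threshold`` passes."""
        return self.max_ag_fraction >= threshold


def max_ag_window(
    sequence_id: str, sequence: str, window: int = DEFAULT_AG_WINDOW
) -> AGWindowResult:
    """Most A/G-rich window of ``window`` nt (exhaustive scan, step 1).

    Ties resolve to the 5'-most start. Sequences shorter than the window are
    scored as a single whole-sequence window and flagged.
    """
    seq = normalize_alphabet(sequence)
    is_ag = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_ag = ((is_ag == ord("A")) | (is_ag == ord("G"))).astype(np.int64)
    n = len(seq)
    if n == 0:
        raise FeatureError(f"empty sequence {sequence_id!r}")
    if n < window:
        return AGWindowResult(
            sequence_id, window, float(is_ag.mean()), 0, whole_sequence=True
        )
    cum = np.concatenate([[0], np.cumsum(is_ag)])
    sums = cum[window:] - cum[:-window]
    start = int(np.argmax(sums))  # argmax returns the first (5'-most) maximum
    return AGWindowResult(sequence_id, window, float(sums[start] / window), start)


def classify_ag_rich(
    utrs: Iterable[tuple[str, str]],
    localized: Mapping[str, bool],
    window: int = DEFAULT_AG_WINDOW,
    threshold: float = DEFAULT_AG_THRESHOLD,
) -> tuple[pd.DataFrame, float, float]:
    """Per-gene A/G-window flag and its association with localization class.

    ``localized`` maps gene id -> bool (e.g. the median-Z >= 2 rule). Returns
    the per-gene table plus the Fisher odds ratio and p-value of the
    class x window-containing contingency.
    """
    rows = []
    for gid, seq in utrs:
        res = max_ag_window(gid, seq, window)
        rows.append(
            {
                "gene_id": gid,
                "max_ag_fraction": res.max_ag_fraction,
                "ag_rich": res.passes(threshold),
                "localized": bool(localized.get(gid, False)),
            }
        )
    df = pd.DataFrame(rows)
    table = np.array(
        [
            [
                int(((df.localized) & (df.ag_rich)).sum()),
                int(((df.localized) & (~df.ag_rich)).sum()),
            ],
            [
                int(((~df.localized) & (df.ag_rich)).sum()),
                int(((~df.localized) & (~df.ag_rich)).sum()),
            ],
        ]
    )
    odds, pvalue = stats.fisher_exact(table)
    return df, float(odds), float(pvalue)


# ---------------------------------------------------------------------------
# kmer enrichment
# ---------------------------------------------------------------------------


def _kmer_counts(sequences: Iterable[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for raw in sequences:
        seq = normalize_alphabet(raw)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(
    fg_sequences: Sequence[str],
    bg_sequences: Sequence[str],
    k: int = 6,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Foreground vs background kmer enrichment (RNA sense strand only).

    log2 enrichment uses symmetric pseudocounts so swapping fg/bg negates it
    exactly; p-values are two-sided binomial tests of the foreground count
    against the background frequency, BH-corrected across all ``4**k`` kmers.
    """
    if not fg_sequences or not bg_sequences:
        raise FeatureError("foreground and background must be non-empty")
    min_len = min(len(s) for s in list(fg_sequences) + list(bg_sequences))
    if k > min_len:
        raise FeatureError(f"k={k} exceeds the shortest sequence ({min_len} nt)")
    fg = _kmer_counts(fg_sequences, k)
    bg = _kmer_counts(bg_sequences, k)
    n_fg = sum(fg.values())
    n_bg = sum(bg.values())
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    n_kmers = len(kmers)
    rows = []
    for kmer in kmers:
        c_fg, c_bg = fg.get(kmer, 0), bg.get(kmer, 0)
        f_fg = (c_fg + pseudocount) / (n_fg + pseudocount * n_kmers)
        f_bg = (c_bg + pseudocount) / (n_bg + pseudocount * n_kmers)
        p_bg = min(max(c_bg / n_bg, 1e-12), 1 - 1e-12)
        pvalue = stats.binomtest(c_fg, n_fg, p_bg).pvalue
        rows.append(
            {
                "kmer": kmer,
                "fg_count": c_fg,
                "bg_count": c_bg,
                "log2_enrichment": float(np.log2(f_fg / f_bg)),
                "pvalue": float(pvalue),
            }
        )
    df = pd.DataFrame(rows)
    from .enrich import bh_adjust

    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    return df.sort_values("log2_enrichment", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------


@dataclass
class FoldProfile:
    sequence_id: str
    window_mfe: list[float]
    median_mfe: float | None
    quadruplex_predicted: bool


def predict_quadruplex(sequence: str) -> bool:
    """Regex fallback for G-quadruplex potential: four G>=3 runs, loops 1-7."""
    return QUADRUPLEX_RE.search(normalize_alphabet(sequence)) is not None


def _external_folder() -> str | None:
    return shutil.which("RNAfold")


def _fold_mfe_external(seqs: Sequence[str], quadruplex: bool) -> list[float]:
    cmd = ["RNAfold", "--noPS"]
    if quadruplex:
        cmd.append("-g")
    proc = subprocess.run(
        cmd, input="\n".join(seqs) + "\n", capture_output=True, text=True, check=True
    )
    mfes = []
    for line in proc.stdout.splitlines():
        m = re.search(r"\(\s*(-?\d+\.\d+)\)\s*$", line)
        if m:
            mfes.append(float(m.group(1)))
    if len(mfes) != len(seqs):
        raise FeatureError("unexpected RNAfold output")
    return mfes


def fold_profile(
    sequence_id: str,
    sequence: str,
    backend: str = "none",
    window: int = FOLD_WINDOW,
    step: int = FOLD_STEP,
) -> FoldProfile:
    """Windowed structure profile: ``window``-nt windows slid ``step`` nt.

    ``backend='external'`` computes per-window MFE with RNAfold and reports
    the median; it raises when the binary is missing (no silent fallback).
    ``backend='none'`` skips MFE and uses the regex quadruplex predictor.
    Sequences shorter than the window are folded as a single whole-sequence
    window.
    """
    seq = normalize_alphabet(sequence)
    if len(seq) >= window:
        windows = [seq[i : i + window] for i in range(0, len(seq) - window + 1, step)]
    else:
        windows = [seq]
    if backend == "external":
        if _external_folder() is None:
            raise FeatureError(
                "backend='external' requires RNAfold on PATH; none found"
            )
        mfes = _fold_mfe_external(windows, quadruplex=False)
        quad = predict_quadruplex(seq)
        return FoldProfile(sequence_id, mfes, float(np.median(mfes)), quad)
    if backend != "none":
        raise FeatureError(f"unknown folding backend {backend!r}")
    return FoldProfile(sequence_id, [], None, predict_quadruplex(seq))
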