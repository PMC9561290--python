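"""Per-oligo neurite-vs-soma differential enrichment and cross-dataset ranking.

The differential test is a negative-binomial Wald test on the neurite/soma
log2 fold change:

1. median-of-ratios size factors (:func:`normalize_counts`);
2. per-oligo method-of-moments dispersions, shrunk in log space toward a
   fitted mean-dispersion trend ``alpha(mu) = a0 + a1/mu``;
3. per-compartment NB means fitted by Fisher scoring with size-factor
   offsets — the two-group design makes the per-group estimates independent,
   so the whole pool is fitted with a handful of vectorized iterations;
4. Wald statistic ``log2fc / se`` referred to a t distribution with
   ``n_samples - 2`` df (slightly conservative at small replicate counts),
   Benjamini-Hochberg correction over the tested rows.

Oligos with fewer than ``min_count`` pooled counts in either compartment are
reported but excluded from testing (``pvalue``/``fdr`` = NaN).

Sign convention: ``log2fc > 0`` means neurite-enriched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: Default pooled-count filter, below which an oligo/gene is not tested.
DEFAULT_MIN_COUNT = 20

#: Z-score threshold above which a gene counts as localized (inclusive).
LOCALIZED_MEDIAN_Z = 2.0


class EnrichError(ValueError):
    pass


@dataclass
class EnrichmentRecord:
    oligo_id: str
    log2fc: float
    se: float
    pvalue: float
    fdr: float
    mean_count: float
    offset: int | None = None  # filled in when joined with a pool manifest

    @property
    def tested(self) -> bool:
        return np.isfinite(self.pvalue)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_counts(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Median-of-ratios size factors and the normalized matrix.

    Size factor of sample *j* is the median over all-nonzero rows of
    ``count_ij / geometric_mean_i``. When no row is nonzero in every sample,
    falls back to total-count scaling with a warning.
    """
    y = counts.counts.astype(float)
    nonzero = np.all(y > 0, axis=1)
    if not nonzero.any():
        warnings.warn(
            "no oligo has nonzero counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = y.sum(axis=0)
        if np.any(totals <= 0):
            raise EnrichError("a sample has zero total counts")
        sf = totals / np.exp(np.mean(np.log(totals)))
    else:
        logs = np.log(y[nonzero])
        log_geomean = logs.mean(axis=1)
        sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return sf, y / sf


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


def _moment_dispersions(
    norm: np.ndarray, groups: Sequence[np.ndarray], inv_sf_mean: float
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments NB dispersion per row, using within-group residuals."""
    n_total = sum(int(g.sum()) for g in groups)
    ss = np.zeros(norm.shape[0])
    mean_of_means = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        gm = sub.mean(axis=1)
        ss += ((sub - gm[:, None]) ** 2).sum(axis=1)
        mean_of_means += gm / len(groups)
    var = ss / max(n_total - len(groups), 1)
    m = np.maximum(mean_of_means, 1e-8)
    alpha = (var - m * inv_sf_mean) / m**2
    return alpha, m


def _fit_dispersion_trend(alpha: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``alpha ~ a0 + a1/mu`` with nonnegative coefficients."""
    ok = (alpha > 1e-6) & (mu > 0)
    if ok.sum() < 3:
        return float(np.median(np.maximum(alpha, 1e-4))), 0.0
    a, x = alpha[ok], 1.0 / mu[ok]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    if a0 < 0:
        a0 = 0.0
        a1 = max(float((x @ a) / (x @ x)), 0.0)
    if a1 < 0:
        a1 = 0.0
        a0 = max(float(a.mean()), 1e-6)
    return max(a0, 0.0), max(a1, 0.0)


def estimate_dispersions(
    norm: np.ndarray,
    groups: Sequence[np.ndarray],
    inv_sf_mean: float,
    shrink_weight: float = 0.5,
) -> np.ndarray:
    """Trend-shrunk dispersions: blend of the per-row moment estimate and the
    fitted trend in log space, floored at the trend to guard against
    underestimated (anticonservative) dispersions."""
    alpha_mom, mu = _moment_dispersions(norm, groups, inv_sf_mean)
    a0, a1 = _fit_dispersion_trend(alpha_mom, mu)
    trend = np.maximum(a0 + a1 / np.maximum(mu, 1e-8), 1e-8)
    raw = np.clip(alpha_mom, 1e-8, 10.0)
    blended = np.exp(
        (1 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend)
    )
    return np.clip(np.maximum(blended, trend), 1e-8, 10.0)


# ---------------------------------------------------------------------------
# NB two-group Wald test
# ---------------------------------------------------------------------------


def _fit_group_log_means(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher scoring for per-row NB log means with offsets log(sf).

    Returns ``(theta, var_theta)`` for one group (columns of ``y``).
    """
    qbar = (y / sf).mean(axis=1)
    theta = np.log(np.maximum(qbar, 1e-6))
    for _ in range(n_iter):
        mu = sf[None, :] * np.exp(theta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = sf[None, :] * np.exp(theta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return theta, 1.0 / np.maximum(info, 1e-12)


def test_enrichment(
    counts: CountMatrix,
    min_count: int = DEFAULT_MIN_COUNT,
    min_count_per_replicate: bool = False,
    shrink_weight: float = 0.5,
) -> list[EnrichmentRecord]:
    """NB Wald test of neurite vs soma abundance for every oligo.

    ``min_count`` filters on pooled per-compartment counts by default (each
    compartment must reach the threshold); ``min_count_per_replicate=True``
    requires it in every replicate instead.
    """
    soma = counts.compartment_mask("soma")
    neur = counts.compartment_mask("neurite")
    if soma.sum() < 2 or neur.sum() < 2:
        raise EnrichError(
            "test_enrichment needs >= 2 replicates per compartment; "
            "use descriptive log2fc for single-replicate data"
        )
    y = counts.counts.astype(float)
    sf, norm = normalize_counts(counts)
    inv_sf_mean = float(np.mean(1.0 / sf))
    alpha = estimate_dispersions(
        norm, [soma, neur], inv_sf_mean, shrink_weight=shrink_weight
    )

    if min_count_per_replicate:
        testable = np.all(y[:, soma] >= min_count, axis=1) & np.all(
            y[:, neur] >= min_count, axis=1
        )
    else:
        testable = (y[:, soma].sum(axis=1) >= min_count) & (
            y[:, neur].sum(axis=1) >= min_count
        )

    theta_s, var_s = _fit_group_log_means(y[:, soma], sf[soma], alpha)
    theta_n, var_n = _fit_group_log_means(y[:, neur], sf[neur], alpha)
    log2fc = (theta_n - theta_s) / LN2
    se = np.sqrt(var_s + var_n) / LN2
    df = int(soma.sum() + neur.sum()) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    pvalue = np.where(testable, 2.0 * stats.t.sf(np.abs(z), df=df), np.nan)
    fdr = np.full_like(pvalue, np.nan)
    fdr[testable] = bh_adjust(pvalue[testable])
    mean_count = norm.mean(axis=1)

    records = []
    for i, oid in enumerate(counts.oligo_ids):
        records.append(
            EnrichmentRecord(
                oligo_id=oid,
                log2fc=float(log2fc[i]),
                se=float(se[i]),
                pvalue=float(pvalue[i]),
                fdr=float(fdr[i]),
                mean_count=float(mean_count[i]),
            )
        )
    return records


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "oligo_id": [r.oligo_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "se": [r.se for r in records],
            "pvalue": [r.pvalue for r in records],
            "fdr": [r.fdr for r in records],
            "mean_count": [r.mean_count for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[EnrichmentRecord]:
    """Adapter for externally produced differential tables.

    Accepts any table with ``oligo_id``, ``log2fc`` and ``padj``/``fdr``
    columns (e.g. another DE engine's output) so the window caller can run on
    it unchanged.
    """
    fdr_col = "fdr" if "fdr" in df.columns else "padj"
    return [
        EnrichmentRecord(
            oligo_id=str(row["oligo_id"]),
            log2fc=float(row["log2fc"]),
            se=float(row.get("se", np.nan)),
            pvalue=float(row.get("pvalue", np.nan)),
            fdr=float(row[fdr_col]),
            mean_count=float(row.get("mean_count", np.nan)),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Cross-dataset Z-score utilities
# ---------------------------------------------------------------------------


@dataclass
class DatasetEnrichmentMatrix:
    enrichments: pd.DataFrame  # genes x datasets
    zscores: pd.DataFrame
    median_z: pd.Series

    def localized(self, threshold: float = LOCALIZED_MEDIAN_Z) -> pd.Series:
        """Boolean classification: localized iff ``median_z >= threshold``."""
        return self.median_z >= threshold


def zscore_datasets(enrichments: pd.DataFrame) -> DatasetEnrichmentMatrix:
    """Z-normalize neurite enrichments within each dataset column and rank
    genes by their NA-aware median Z across datasets (descending)."""
    if enrichments.shape[0] < 2:
        raise EnrichError("need >= 2 genes per dataset to z-normalize")
    z = enrichments.copy().astype(float)
    for col in z.columns:
        vals = z[col]
        sd = vals.std(ddof=0)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"dataset {col!r} is constant; z-scores set to 0", stacklevel=2)
            z[col] = np.where(vals.notna(), 0.0, np.nan)
        else:
            z[col] = (vals - vals.mean()) / sd
    median_z = z.median(axis=1, skipna=True).sort_values(ascending=False)
    return DatasetEnrichmentMatrix(
        enrichments=enrichments, zscores=z, median_z=median_z
    )


# ---------------------------------------------------------------------------
# RT-qPCR ratio of ratios
# ---------------------------------------------------------------------------


def ratio_of_ratios(
    ct_reporter_soma: Sequence[float],
    ct_control_soma: Sequence[float],
    ct_reporter_neurite: Sequence[float],
    ct_control_neurite: Sequence[float],
) -> tuple[np.ndarray, float, float]:
    """Delta-delta-Ct fold enrichment from replicate Ct quadruples.

    ``fold = 2 ** -((Ct_rep - Ct_ctrl)_neurite - (Ct_rep - Ct_ctrl)_soma)``
    per replicate; returns ``(folds, mean, sd)``.
    """
    arrays = [
        np.asarray(a, dtype=float)
        for a in (
            ct_reporter_soma, ct_control_soma, ct_reporter_neurite, ct_control_neurite
        )
    ]
    if any(a.size == 0 for a in arrays):
        raise EnrichError("all four Ct series are required")
    if len({a.size for a in arrays}) != 1:
        raise EnrichError("Ct series must have equal replicate counts")
    if any(np.any(a <= 0) for a in arrays):
        raise EnrichError("Ct values must be positive")
    rs, cs, rn, cn = arrays
    ddct = (rn - cn) - (rs - cs)
    folds = np.exp2(-ddct)
    return folds, float(folds.mean()), float(folds.std(ddof=1) if folds.size > 1 else 0.0)
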