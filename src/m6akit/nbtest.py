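"""Negative-binomial count statistics shared by all contrasts.

Median-of-ratios normalization, method-of-moments dispersion with
decile-trend shrinkage, and a two-group NB Wald test with a log link and
log-size-factor offset. The same engine drives IP-vs-input m6A enrichment
and KO-vs-WT expression contrasts; the group named first in the contrast
is always the numerator of the reported fold change.

Model per gene: counts ~ NB(mean = s_j * q_group, variance = mu + alpha*mu^2).
The two-group design is saturated at the group level, so each group mean is
fit by Fisher scoring on its own and the Wald SE comes from the observed
information, se(beta)^2 = 1/sum_A(w) + 1/sum_B(w) with w = mu/(1+alpha*mu).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError, ParameterError
from .io import CountMatrix

LN2 = np.log(2.0)

#: genes with total contrast count below this are not tested
DEFAULT_MIN_TOTAL_COUNT = 10

_MAX_ITER = 50
_TOL = 1e-10


# ---------------------------------------------------------------------------
# Size factors (median-of-ratios, geometric mean 1)
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero count in any sample are excluded from the medians.

    Raises
    ------
    NormalizationError
        If no gene has positive counts in every sample.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no gene has nonzero counts in all samples; filter the matrix or "
            "merge samples before normalizing"
        )
    sub = mat[all_pos]
    log_geo_mean = np.log(sub).mean(axis=1)
    log_ratios = np.log(sub) - log_geo_mean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# Dispersion (method of moments, pooled within groups)
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: CountMatrix | np.ndarray,
                        groups: Sequence,
                        size_factors_: np.ndarray,
                        shrink: bool = True) -> np.ndarray:
    """Per-gene NB dispersion alpha (variance = mu + alpha*mu^2).

    Method of moments on normalized counts: the within-group variance is
    pooled across groups and alpha_hat = max(0, (s^2 - mean)/mean^2); genes
    with zero mean get alpha 0. With ``shrink=True`` the raw estimate is
    averaged 50/50 with the mean raw dispersion of the gene's
    expression-decile, which stabilizes the tiny-replicate case.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    groups = np.asarray(groups)
    if mat.shape[1] != groups.shape[0]:
        raise ParameterError("groups length must match sample count")
    if mat.shape[1] < 2:
        raise ParameterError("dispersion estimation needs >=2 samples")
    norm = mat / np.asarray(size_factors_, dtype=float)[None, :]

    levels = np.unique(groups)
    ss = np.zeros(mat.shape[0])
    df = 0
    for lev in levels:
        cols = norm[:, groups == lev]
        if cols.shape[1] >= 2:
            ss += ((cols - cols.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += cols.shape[1] - 1
    mean = norm.mean(axis=1)
    if df == 0:
        return np.zeros(mat.shape[0])
    var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mean > 0, np.maximum(0.0, (var - mean) / mean**2), 0.0)

    if shrink and mat.shape[0] >= 10:
        order = np.argsort(np.argsort(mean, kind="stable"), kind="stable")
        decile = np.minimum(9, (order * 10) // mat.shape[0])
        decile_mean = np.zeros(10)
        for d in range(10):
            sel = decile == d
            if sel.any():
                decile_mean[d] = alpha[sel].mean()
        alpha = 0.5 * alpha + 0.5 * decile_mean[decile]
    return alpha


# ---------------------------------------------------------------------------
# Two-group NB Wald test
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Per-gene output of the two-group NB Wald test.

    ``wald_stat`` is the coefficient over its standard error; ``log2fc`` is
    oriented so that the first (numerator) group over the second is positive.
    """

    table: pd.DataFrame  # gene_id, base_mean, log2fc, se, wald_stat, p_value, padj, n_eff, flag

    def __len__(self) -> int:
        return len(self.table)


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray):
    """Vectorized Fisher scoring for q in counts ~ NB(s_j*q, alpha), per gene.

    Returns (log q, sum of working weights w = mu/(1+alpha*mu), converged).
    """
    naive = (y / s[None, :]).mean(axis=1)
    theta = np.log(np.maximum(naive, 1e-8))
    converged = np.zeros(y.shape[0], dtype=bool)
    for _ in range(_MAX_ITER):
        mu = s[None, :] * np.exp(theta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        theta = theta + np.where(converged, 0.0, step)
        converged |= np.abs(step) < _TOL
        if converged.all():
            break
    mu = s[None, :] * np.exp(theta)[:, None]
    wsum = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return theta, wsum, converged


def nb_wald_test(counts: CountMatrix,
                 groups: Sequence,
                 size_factors_: np.ndarray,
                 dispersion: np.ndarray,
                 numerator: object = None,
                 min_total_count: int = DEFAULT_MIN_TOTAL_COUNT) -> EnrichmentResult:
    """Two-group NB Wald test per gene.

    Parameters
    ----------
    groups
        Length-``n_samples`` labels with exactly two levels.
    numerator
        Which group label forms the numerator of the fold change
        (default: first label in ``groups`` order).
    min_total_count
        Genes with total count across the contrast below this are excluded
        from the result (low-count filter).

    Notes
    -----
    When one group is all zeros for a gene, a continuity correction spreads
    +0.5 over each group's samples (so each group total gains 0.5) and the
    gene is flagged ``zero_group``; non-converged fits fall back to the
    closed-form ratio-of-normalized-means estimate and are flagged.
    """
    groups = np.asarray([str(g) for g in groups])
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ParameterError(f"need exactly two group levels, got {levels}")
    num = str(numerator) if numerator is not None else levels[0]
    if num not in levels:
        raise ParameterError(f"numerator {num!r} not among group levels {levels}")
    den = levels[0] if levels[1] == num else levels[1]
    a_idx = groups == num
    b_idx = groups == den
    if not a_idx.any() or not b_idx.any():
        raise ParameterError("both groups must be non-empty")

    s = np.asarray(size_factors_, dtype=float)
    if (s <= 0).any():
        raise ParameterError("size factors must be positive")
    mat = counts.counts.astype(float)
    alpha = np.asarray(dispersion, dtype=float)
    if (alpha < 0).any():
        raise ParameterError("dispersion must be nonnegative")

    keep = mat.sum(axis=1) >= min_total_count
    genes = [g for g, k in zip(counts.gene_ids, keep) if k]
    y = mat[keep]
    alpha = alpha[keep]
    n_genes = y.shape[0]

    flags = np.array([""] * n_genes, dtype=object)
    ya = y[:, a_idx].copy()
    yb = y[:, b_idx].copy()
    zero_a = ya.sum(axis=1) == 0
    zero_b = yb.sum(axis=1) == 0
    zero_any = zero_a | zero_b
    if zero_any.any():
        # +0.5 to each group total, spread uniformly over the group's samples
        ya[zero_any] += 0.5 / ya.shape[1]
        yb[zero_any] += 0.5 / yb.shape[1]
        flags[zero_any] = "zero_group"

    theta_a, wsum_a, conv_a = _fit_group_mean(ya, s[a_idx], alpha)
    theta_b, wsum_b, conv_b = _fit_group_mean(yb, s[b_idx], alpha)
    converged = conv_a & conv_b

    # fallback: closed-form ratio of normalized group means
    if not converged.all():
        bad = ~converged
        na = (ya[bad] / s[a_idx][None, :]).mean(axis=1)
        nb = (yb[bad] / s[b_idx][None, :]).mean(axis=1)
        theta_a = theta_a.copy()
        theta_b = theta_b.copy()
        theta_a[bad] = np.log(np.maximum(na, 1e-12))
        theta_b[bad] = np.log(np.maximum(nb, 1e-12))
        flags[bad] = np.where(flags[bad] == "", "fallback_ratio", flags[bad] + "+fallback_ratio")

    beta = theta_a - theta_b  # natural log fold change, numerator over denominator
    with np.errstate(divide="ignore", invalid="ignore"):
        se_nat = np.sqrt(1.0 / np.maximum(wsum_a, 1e-300)
                         + 1.0 / np.maximum(wsum_b, 1e-300))
    log2fc = beta / LN2
    se = se_nat / LN2
    wald = np.where(se_nat > 0, beta / se_nat, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))

    unusable = ~np.isfinite(wald)
    if unusable.any():
        wald[unusable] = 0.0
        p[unusable] = 1.0
        flags[unusable] = "no_fit"

    base_mean = (y / s[None, :]).mean(axis=1)
    table = pd.DataFrame({
        "gene_id": genes,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "wald_stat": wald,
        "p_value": np.clip(p, 0.0, 1.0),
        "padj": benjamini_hochberg(np.clip(p, 0.0, 1.0)),
        "n_eff": int(a_idx.sum() + b_idx.sum()),
        "flag": flags,
    })
    return EnrichmentResult(table)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def ip_input_contrast(counts: CountMatrix, sheet, population: str,
                      condition: str | None = None,
                      min_total_count: int = DEFAULT_MIN_TOTAL_COUNT,
                      shrink: bool = True) -> EnrichmentResult:
    """IP-vs-input enrichment for one population (IP is the numerator)."""
    ip = sheet.samples_for(population=population, assay="IP", condition=condition)
    inp = sheet.samples_for(population=population, assay="INPUT", condition=condition)
    if not ip or not inp:
        raise ParameterError(
            f"population {population!r} lacks IP or INPUT samples"
        )
    sub = counts.subset_samples(ip + inp)
    groups = ["IP"] * len(ip) + ["INPUT"] * len(inp)
    sf = size_factors(sub)
    disp = estimate_dispersion(sub, groups, sf, shrink=shrink)
    return nb_wald_test(sub, groups, sf, disp, numerator="IP",
                        min_total_count=min_total_count)


def condition_contrast(counts: CountMatrix, sheet, numerator: str = "KO",
                       denominator: str = "WT", assay: str = "INPUT",
                       population: str | None = None,
                       min_total_count: int = DEFAULT_MIN_TOTAL_COUNT,
                       shrink: bool = True) -> EnrichmentResult:
    """Condition contrast (KO vs WT by default) on one assay stratum."""
    a = sheet.samples_for(population=population, assay=assay, condition=numerator)
    b = sheet.samples_for(population=population, assay=assay, condition=denominator)
    if not a or not b:
        raise ParameterError(
            f"missing samples for contrast {numerator} vs {denominator}"
        )
    sub = counts.subset_samples(a + b)
    groups = [numerator] * len(a) + [denominator] * len(b)
    sf = size_factors(sub)
    disp = estimate_dispersion(sub, groups, sf, shrink=shrink)
    return nb_wald_test(sub, groups, sf, disp, numerator=numerator,
                        min_total_count=min_total_count)
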