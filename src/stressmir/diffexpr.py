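"""Normalization, contrasts, multiple-testing correction, QC, and the ddCt helper.

Fold changes are control-relative: each condition's mean normalized count is
divided by the control mean and log2-transformed.  Two per-miRNA tests are
available for a contrast of condition b against condition a:

``exact``
    Two-sided exact conditional binomial test: replicate counts are pooled
    within each side, and conditional on the pooled total the side-b count
    is Binomial(n, pi) under the null, with pi the side-b share of the
    effective (size-factor-summed) library.  Exact for Poisson counts;
    anti-conservative when counts carry biological overdispersion.

``nb_wald``
    Overdispersion-aware Wald test on log mean normalized counts, with a
    single common negative-binomial dispersion estimated across all miRNAs
    and conditions by moment matching.  Appropriate for replicated counts
    with biological variability.

q-values are Benjamini-Hochberg adjusted within each contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .data import ContrastResult, CountMatrix, resolve_condition

# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def filter_detected(cm: CountMatrix, mode: str = "all_samples") -> CountMatrix:
    """Remove miRNAs without reads in every biological replicate.

    ``mode="all_samples"`` (the strict default) keeps miRNAs with count >= 1
    in every sample; ``mode="any_condition"`` keeps miRNAs detected in every
    replicate of at least one condition.
    """
    c = cm.counts
    if len(c) == 0:
        return cm
    if mode == "all_samples":
        keep = (c >= 1).all(axis=1)
    elif mode == "any_condition":
        keep = pd.Series(False, index=c.index)
        for cond in cm.conditions:
            cols = cm.condition_samples(cond)
            keep |= (c[cols] >= 1).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CountMatrix(c.loc[keep], cm.samples)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Per-sample depth factors: column total / mean of column totals."""
    totals = cm.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total samples: {bad}")
    return totals / totals.mean()


def median_ratio_size_factors(cm: CountMatrix) -> pd.Series:
    """Composition-robust depth factors (median-of-ratios, DESeq-style).

    factor_s = median over miRNAs of count_{ms} / (geometric mean of miRNA m
    across samples), using miRNAs with nonzero counts everywhere; rescaled
    to mean 1.  Unlike total-count factors, this is insensitive to a
    minority of strongly regulated miRNAs inflating some libraries, which
    otherwise imprints a spurious shift on every unregulated miRNA.
    """
    counts = cm.counts.to_numpy(dtype=float)
    ok = (counts > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no miRNA has nonzero counts in every sample")
    logc = np.log(counts[ok])
    logref = logc.mean(axis=1)
    factors = np.exp(np.median(logc - logref[:, None], axis=0))
    factors = factors / factors.mean()
    return pd.Series(factors, index=cm.counts.columns)


def compute_size_factors(cm: CountMatrix, method: str = "median_ratio") -> pd.Series:
    """Dispatch on normalization method: ``"total"`` or ``"median_ratio"``."""
    if method == "total":
        return size_factors(cm)
    if method == "median_ratio":
        return median_ratio_size_factors(cm)
    raise ValueError(f"unknown normalization method {method!r}")


def normalize(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Depth-normalized counts: raw / size factor."""
    if factors is None:
        factors = size_factors(cm)
    return cm.counts / factors


# ---------------------------------------------------------------------------
# Dispersion and tests
# ---------------------------------------------------------------------------


def estimate_dispersion(cm: CountMatrix, factors: pd.Series | None = None) -> float:
    """Common NB dispersion by moment matching on normalized counts.

    Pools (s^2 - m) against m^2 over every miRNA x condition cell with >= 2
    replicates, via a regression through the origin; clipped at 0 (Poisson).
    """
    norm = normalize(cm, factors)
    num = 0.0
    den = 0.0
    for cond in cm.conditions:
        cols = cm.condition_samples(cond)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(((v - m) * m**2)[ok].sum())
        den += float((m**4)[ok].sum())
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _exact_binomial_p(x_a: np.ndarray, x_b: np.ndarray, share_b: float) -> np.ndarray:
    """Two-sided exact binomial p-values (minimum-likelihood two-sided rule)."""
    pvals = np.ones(len(x_a))
    for i, (a, b) in enumerate(zip(x_a, x_b)):
        n = int(round(a + b))
        if n == 0:
            continue
        pvals[i] = stats.binomtest(int(round(b)), n, share_b).pvalue
    return np.minimum(pvals, 1.0)


def _nb_wald_p(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    n_a: int,
    n_b: int,
    dispersion: float,
) -> np.ndarray:
    """Wald test on log mean normalized counts with common NB dispersion.

    Delta method: Var(log m) ~ (1/n) (1/mu + alpha).  Zero-mean sides are
    floored at 0.5 for the test only.
    """
    ma = np.maximum(mean_a, 0.5)
    mb = np.maximum(mean_b, 0.5)
    var = (1.0 / ma + dispersion) / n_a + (1.0 / mb + dispersion) / n_b
    z = (np.log(mb) - np.log(ma)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mean_a == 0) & (mean_b == 0)
    p[both_zero] = 1.0
    return np.minimum(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    method: str = "exact",
    dispersion: float | None = None,
    factors: pd.Series | None = None,
    pseudocount: float = 0.0,
) -> ContrastResult:
    """Per-miRNA fold change and significance for condition_b vs condition_a.

    log2FC = log2(mean normalized count in b / mean normalized count in a),
    optionally stabilised by ``pseudocount`` on both sides.  p-values come
    from the selected test; q-values are BH-adjusted over all miRNAs in this
    contrast.
    """
    condition_a = resolve_condition(condition_a)
    condition_b = resolve_condition(condition_b)
    cols_a = cm.condition_samples(condition_a)
    cols_b = cm.condition_samples(condition_b)
    if not cols_a or not cols_b:
        raise ValueError("both conditions must have samples")
    if factors is None:
        factors = size_factors(cm)
    norm = cm.counts / factors
    mean_a = norm[cols_a].mean(axis=1).to_numpy()
    mean_b = norm[cols_b].mean(axis=1).to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    if method == "exact":
        x_a = cm.counts[cols_a].sum(axis=1).to_numpy()
        x_b = cm.counts[cols_b].sum(axis=1).to_numpy()
        s_a = float(factors[cols_a].sum())
        s_b = float(factors[cols_b].sum())
        p = _exact_binomial_p(x_a, x_b, s_b / (s_a + s_b))
    elif method == "nb_wald":
        if dispersion is None:
            dispersion = estimate_dispersion(cm, factors)
        p = _nb_wald_p(mean_a, mean_b, len(cols_a), len(cols_b), dispersion)
    else:
        raise ValueError(f"unknown test method {method!r}")

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": lfc,
            "pvalue": p,
            "qvalue": bh_adjust(p),
        },
        index=cm.counts.index,
    )
    extra = {"dispersion": dispersion} if method == "nb_wald" else {}
    return ContrastResult(condition_a, condition_b, table, method=method, extra=extra)


# ---------------------------------------------------------------------------
# QC and reporting helpers
# ---------------------------------------------------------------------------


def replicate_qc(cm: CountMatrix) -> dict:
    """Replicate concordance and a sample dendrogram.

    Returns a dict with ``r_squared`` (condition -> R^2 of log2(count+1)
    replicate 2 regressed on replicate 1; None when a condition has a single
    replicate), ``linkage`` (scipy average-linkage matrix on 1 - Pearson
    correlation of log counts) and ``order`` (leaf sample ids).
    """
    logc = np.log2(normalize(cm) + 1.0)
    r2: dict[str, float | None] = {}
    for cond in cm.conditions:
        cols = cm.condition_samples(cond)
        if len(cols) < 2:
            r2[cond] = None
            continue
        x = logc[cols[0]].to_numpy()
        y = logc[cols[1]].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r2[cond] = 1.0 if np.array_equal(x, y) else 0.0
        else:
            r2[cond] = float(np.corrcoef(x, y)[0, 1] ** 2)
    corr = np.corrcoef(logc.to_numpy().T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [logc.columns[i] for i in hierarchy.leaves_list(link)]
    return {"r_squared": r2, "linkage": link, "order": order}


def volcano_table(
    result: ContrastResult, alpha: float = 0.05, cap: float = 300.0
) -> pd.DataFrame:
    """Volcano-plot rows: log2FC, -log10 q (capped), strict q < alpha flag."""
    q = result["qvalue"].to_numpy()
    with np.errstate(divide="ignore"):
        neg = -np.log10(q)
    neg = np.minimum(neg, cap)
    return pd.DataFrame(
        {
            "log2fc": result["log2fc"].to_numpy(),
            "neg_log10_q": neg,
            "significant": q < alpha,
        },
        index=result.mirnas,
    )


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Comparative Ct fold change, 2^(-ddCt).

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control.
    The reference is a stably expressed normalizer (miR-2-5p in the study).
    """
    cts = (
        ct_target_treated,
        ct_reference_treated,
        ct_target_control,
        ct_reference_control,
    )
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )
    return float(2.0 ** (-ddct))
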