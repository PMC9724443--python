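"""Differential expression and differential splicing tests.

Differential expression uses a negative-binomial Wald test on
median-of-ratios normalised counts with a method-of-moments dispersion
estimate shrunk towards a fitted mean-dispersion trend; a gene is called
differentially expressed (DEG) when |log2FC| >= 1 and BH-adjusted p (FDR)
< 0.05.

Differential splicing compares, per event, a shared-inclusion binomial
model against condition-specific inclusion on replicate-pooled junction
counts (likelihood-ratio test, chi-square with 1 df); an event is called
differentially spliced (DAS) when FDR < 0.05. Delta-PSI is the difference
of condition means of per-sample PSI (condition2 minus condition1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .quantify import estimate_psi


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    Input order is preserved; ties are handled stably.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors.

    Uses genes with all-positive counts; falls back to total-count ratios
    when no such gene exists.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 1:
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1, keepdims=True)  # log geometric mean per gene
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return sf


def _fit_dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit disp ~ a0 + a1/mu by least squares over informative genes."""
    ok = (mu > 0) & (disp > 0)
    if ok.sum() < 10:
        return np.full_like(mu, max(float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01, 1e-8))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    a0 = max(coef[0], 1e-8)
    a1 = max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        return a0 + a1 / np.maximum(mu, 1e-8)


def test_differential_expression(
    counts: pd.DataFrame,
    design: pd.Series,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB Wald test of condition2 vs condition1.

    Parameters
    ----------
    counts : gene x sample integer counts.
    design : sample -> condition label; exactly two conditions, each with
        >= 2 replicates. Conditions are ordered by sorted label; log2FC is
        second vs first.

    Returns a DataFrame with columns base_mean, log2fc, pvalue, padj, deg.
    """
    design = design.reindex(counts.columns)
    conds = sorted(design.unique())
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    g1 = counts.columns[design == conds[0]]
    g2 = counts.columns[design == conds[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each condition needs at least two replicates")
    mat = counts.to_numpy(dtype=float)
    if mat.sum(axis=0).min() <= 0:
        raise ValueError("a library has zero total counts")
    sf = size_factors(mat)
    norm = mat / sf[None, :]
    i1 = [counts.columns.get_loc(s) for s in g1]
    i2 = [counts.columns.get_loc(s) for s in g2]
    n1, n2 = len(i1), len(i2)
    mu1 = norm[:, i1].mean(axis=1)
    mu2 = norm[:, i2].mean(axis=1)
    mu = norm.mean(axis=1)
    # pooled within-condition variance, method-of-moments dispersion
    var_within = (
        norm[:, i1].var(axis=1, ddof=1) * (n1 - 1)
        + norm[:, i2].var(axis=1, ddof=1) * (n2 - 1)
    ) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(mu > 0, (var_within - mu) / mu**2, 0.0)
    disp_mom = np.clip(disp_mom, 0.0, 10.0)
    disp_trend = _fit_dispersion_trend(mu, disp_mom)
    disp = np.clip(np.maximum(disp_mom, disp_trend), 1e-8, 10.0)

    pc = 0.5  # pseudocount stabilising log fold changes of low counts
    log2fc = np.log2((mu2 + pc) / (mu1 + pc))
    var_log1 = (1.0 / (mu1 + pc) + disp) / n1
    var_log2 = (1.0 / (mu2 + pc) + disp) / n2
    se_ln = np.sqrt(var_log1 + var_log2)
    z = (np.log(mu2 + pc) - np.log(mu1 + pc)) / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    informative = (mu1 + mu2) > 0
    pvalue = np.where(informative, pvalue, 1.0)
    padj = np.ones_like(pvalue)
    padj[informative] = benjamini_hochberg(pvalue[informative])
    deg = (np.abs(log2fc) >= lfc_threshold) & (padj < alpha)
    return pd.DataFrame(
        {
            "base_mean": mu,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "deg": deg,
        },
        index=counts.index.rename("gene_id"),
    )


def _row_mean_ignoring_nan(x: np.ndarray) -> np.ndarray:
    n = (~np.isnan(x)).sum(axis=1)
    total = np.nansum(x, axis=1)
    return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def _binom_loglik(I, N):
    """Max binomial log-likelihood of I successes in N trials (vectorised)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return special.xlogy(I, I / N) + special.xlogy(N - I, 1 - I / N)


def test_differential_psi(
    event_counts: pd.DataFrame,
    event_lengths: pd.DataFrame,
    design: pd.Series,
    min_total: int = 10,
    min_samples: int = 2,
    alpha: float = 0.05,
    delta_psi_min: float = 0.0,
) -> pd.DataFrame:
    """Pooled binomial likelihood-ratio test of inclusion per event.

    Replicates are pooled within condition; the LRT compares a shared
    inclusion proportion against condition-specific proportions, with p
    from chi-square(1). Events with a defined PSI (I+S >= ``min_total``)
    in fewer than ``min_samples`` samples of either condition are reported
    untested (NaN p, excluded from the BH family).

    Returns a DataFrame indexed by event_id with columns psi_<cond1>,
    psi_<cond2>, delta_psi, lr_stat, pvalue, padj, das, direction, tested.
    """
    I = event_counts.pivot(index="event_id", columns="sample_id", values="inclusion_count")
    S = event_counts.pivot(index="event_id", columns="sample_id", values="skipping_count")
    design = design.reindex(I.columns)
    conds = sorted(design.unique())
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    c1 = I.columns[design == conds[0]]
    c2 = I.columns[design == conds[1]]
    l_I = event_lengths["inclusion_length"].reindex(I.index).to_numpy(dtype=float)
    l_S = event_lengths["skipping_length"].reindex(I.index).to_numpy(dtype=float)

    Iv, Sv = I.to_numpy(dtype=float), S.to_numpy(dtype=float)
    covered = (Iv + Sv) >= min_total
    idx1 = [I.columns.get_loc(s) for s in c1]
    idx2 = [I.columns.get_loc(s) for s in c2]
    tested = (covered[:, idx1].sum(axis=1) >= min_samples) & (
        covered[:, idx2].sum(axis=1) >= min_samples
    )

    psi = estimate_psi(Iv, Sv, l_I[:, None], l_S[:, None], min_total=min_total)
    psi1 = _row_mean_ignoring_nan(psi[:, idx1])
    psi2 = _row_mean_ignoring_nan(psi[:, idx2])
    delta = psi2 - psi1

    I1, S1 = Iv[:, idx1].sum(axis=1), Sv[:, idx1].sum(axis=1)
    I2, S2 = Iv[:, idx2].sum(axis=1), Sv[:, idx2].sum(axis=1)
    N1, N2 = I1 + S1, I2 + S2
    ll_sep = _binom_loglik(I1, N1) + _binom_loglik(I2, N2)
    ll_shared = _binom_loglik(I1 + I2, N1 + N2)
    lr = np.maximum(2.0 * (ll_sep - ll_shared), 0.0)
    lr = np.where(np.isfinite(lr), lr, 0.0)
    pvalue = np.where(tested, stats.chi2.sf(lr, df=1), np.nan)
    padj = np.full_like(pvalue, np.nan)
    if tested.any():
        padj[tested] = benjamini_hochberg(pvalue[tested])
    das = np.where(
        tested,
        (padj < alpha) & (np.abs(delta) >= delta_psi_min),
        False,
    ).astype(bool)
    direction = np.where(delta > 0, "increased", np.where(delta < 0, "decreased", "unchanged"))
    return pd.DataFrame(
        {
            f"psi_{conds[0]}": psi1,
            f"psi_{conds[1]}": psi2,
            "delta_psi": delta,
            "lr_stat": lr,
            "pvalue": pvalue,
            "padj": padj,
            "das": das,
            "direction": direction,
            "tested": tested,
        },
        index=I.index,
    )


def intersect_deg_dasg(deg_genes, das_genes) -> dict:
    """Venn counts and the sorted intersection of DEG and DAS gene sets."""
    deg = set(deg_genes)
    das = set(das_genes)
    inter = sorted(deg & das)
    return {
        "n_deg": len(deg),
        "n_dasg": len(das),
        "n_intersection": len(inter),
        "intersection": inter,
    }
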