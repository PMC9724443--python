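"""MeRIP-seq enrichment analysis.

Peak calling scans fixed-width genomic bins and tests, per condition, IP
versus input enrichment with a one-sided Fisher exact test (computed via
the hypergeometric tail) on replicate-pooled counts. Bins with BH-adjusted
p < alpha and fold enrichment >= ``min_fold`` are merged when adjacent,
and the per-condition peak sets are unioned into a single testing family.

The m6A enrichment level of a region is MFPKM = FPKM_IP / FPKM_INPUT,
computed per replicate and averaged across a condition's replicates
(replicates with zero input coverage are excluded). Differential
methylation compares conditions with a two-sided Fisher test on pooled
(IP, input) counts; log2FC is log2(MFPKM_cond2 / MFPKM_cond1), with
cond2 hypermethylated when log2FC > 0.

All intervals are 0-based half-open (BED semantics): intervals touching
only at a boundary point do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

_BIN_META = ["chrom", "start", "end", "gene_id"]


def _pool(counts: pd.DataFrame, samples) -> np.ndarray:
    return counts[list(samples)].sum(axis=1).to_numpy(dtype=float)


def _one_sided_enrichment_p(k_ip, ip_total, k_in, in_total) -> np.ndarray:
    """P(X >= k_ip) under the Fisher/hypergeometric null of no enrichment.

    Population = all pooled reads; successes = IP reads; draws = reads in
    the bin. Vectorised over bins.
    """
    M = ip_total + in_total
    draws = k_ip + k_in
    return stats.hypergeom.sf(k_ip - 1, int(M), int(ip_total), draws.astype(int))


def call_peaks(
    bins: pd.DataFrame,
    ip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    design: pd.Series,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Call enriched windows per condition and union them into peaks.

    Parameters
    ----------
    bins : bin metadata (chrom, start, end, gene_id) indexed by bin_id;
        IP and input count tables must share this index and their sample
        columns must match pairwise (paired libraries per replicate).
    design : sample -> condition label.

    Returns
    -------
    (peaks, peak_ip, peak_input) where ``peaks`` has peak_id, chrom,
    start, end, gene_id and per-condition significance columns, and the
    count tables hold per-sample counts re-aggregated over merged bins.
    """
    if not bins.index.equals(ip_counts.index) or not bins.index.equals(input_counts.index):
        raise ValueError("IP and input tables must share the bin grid")
    if list(ip_counts.columns) != list(input_counts.columns):
        raise ValueError("IP and input sample columns must be paired")
    design = design.reindex(ip_counts.columns)
    conds = sorted(design.unique())

    sig_by_cond = {}
    for cond in conds:
        samples = ip_counts.columns[design == cond]
        ip = _pool(ip_counts, samples)
        inp = _pool(input_counts, samples)
        ip_total, in_total = ip.sum(), inp.sum()
        covered = (ip + inp) > 0
        p = np.ones(len(bins))
        p[covered] = _one_sided_enrichment_p(
            ip[covered], ip_total, inp[covered], in_total
        )
        padj = np.ones(len(bins))
        from .differential import benjamini_hochberg

        padj[covered] = benjamini_hochberg(p[covered])
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = (ip / ip_total) / (inp / in_total)
        fold = np.where(inp == 0, np.where(ip > 0, np.inf, 0.0), fold)
        sig_by_cond[cond] = (padj < alpha) & (fold >= min_fold) & covered

    any_sig = np.zeros(len(bins), dtype=bool)
    for m in sig_by_cond.values():
        any_sig |= m
    sig_bins = bins.loc[any_sig].sort_values(["chrom", "start"])

    # merge runs of adjacent significant bins on the same chromosome
    peaks = []
    members: list[list] = []
    for bin_id, row in sig_bins.iterrows():
        if peaks and row["chrom"] == peaks[-1]["chrom"] and row["start"] <= peaks[-1]["end"]:
            peaks[-1]["end"] = max(peaks[-1]["end"], row["end"])
            members[-1].append(bin_id)
        else:
            peaks.append(
                {
                    "chrom": row["chrom"],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "gene_id": row["gene_id"],
                }
            )
            members.append([bin_id])

    records, ip_rows, input_rows, ids = [], [], [], []
    for peak, bin_ids in zip(peaks, members):
        pid = f"peak:{peak['chrom']}:{peak['start']}-{peak['end']}"
        ids.append(pid)
        rec = dict(peak_id=pid, **peak)
        for cond in conds:
            rec[f"called_{cond}"] = bool(sig_by_cond[cond][bins.index.get_indexer(bin_ids)].any())
        records.append(rec)
        ip_rows.append(ip_counts.loc[bin_ids].sum(axis=0))
        input_rows.append(input_counts.loc[bin_ids].sum(axis=0))
    peaks_df = pd.DataFrame(records, columns=["peak_id", *_BIN_META, *(f"called_{c}" for c in conds)])
    peaks_df = peaks_df.set_index("peak_id")
    peak_ip = pd.DataFrame(ip_rows, index=ids, columns=ip_counts.columns)
    peak_input = pd.DataFrame(input_rows, index=ids, columns=input_counts.columns)
    return peaks_df, peak_ip, peak_input


def compute_mfpkm(
    ip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    design: pd.Series,
    ip_library_sizes: pd.Series | None = None,
    input_library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean per-replicate FPKM_IP / FPKM_INPUT ratio per condition.

    Region length cancels in the ratio, so only library sizes enter.
    Replicates with zero input coverage in a region are excluded from the
    mean (logged); a region undefined in every replicate of a condition
    gets NaN.
    """
    if ip_library_sizes is None:
        ip_library_sizes = ip_counts.sum(axis=0)
    if input_library_sizes is None:
        input_library_sizes = input_counts.sum(axis=0)
    design = design.reindex(ip_counts.columns)
    out = {}
    n_excluded = 0
    for cond in sorted(design.unique()):
        samples = ip_counts.columns[design == cond]
        ratios = []
        for s in samples:
            fpkm_ip = ip_counts[s] / (ip_library_sizes[s] / 1e6)
            fpkm_in = input_counts[s] / (input_library_sizes[s] / 1e6)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = fpkm_ip / fpkm_in
            undefined = input_counts[s] == 0
            n_excluded += int(undefined.sum())
            ratios.append(r.mask(undefined))
        out[cond] = pd.concat(ratios, axis=1).mean(axis=1, skipna=True)
    if n_excluded:
        logger.warning("MFPKM: excluded %d zero-input replicate ratios", n_excluded)
    return pd.DataFrame(out)


def test_differential_methylation(
    ip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    design: pd.Series,
    alpha: float = 0.05,
    ip_library_sizes: pd.Series | None = None,
    input_library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-region differential m6A enrichment between two conditions.

    log2FC = log2(MFPKM_cond2 / MFPKM_cond1); p from a two-sided Fisher
    test on the pooled 2x2 table of (IP, input) counts per condition; BH
    across regions with defined MFPKM in both conditions. Direction is
    hyper (log2FC > 0) or hypo (log2FC < 0) in cond2 vs cond1.
    """
    design = design.reindex(ip_counts.columns)
    conds = sorted(design.unique())
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    mfpkm = compute_mfpkm(
        ip_counts, input_counts, design, ip_library_sizes, input_library_sizes
    )
    m1, m2 = mfpkm[conds[0]], mfpkm[conds[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(m2 / m1)
    tested = m1.notna() & m2.notna() & (m1 > 0) & (m2 > 0)

    s1 = ip_counts.columns[design == conds[0]]
    s2 = ip_counts.columns[design == conds[1]]
    ip1, in1 = _pool(ip_counts, s1), _pool(input_counts, s1)
    ip2, in2 = _pool(ip_counts, s2), _pool(input_counts, s2)
    pvals = np.full(len(ip_counts), np.nan)
    for i in np.flatnonzero(tested.to_numpy()):
        table = [[int(ip2[i]), int(in2[i])], [int(ip1[i]), int(in1[i])]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    padj = np.full_like(pvals, np.nan)
    mask = tested.to_numpy()
    if mask.any():
        from .differential import benjamini_hochberg

        padj[mask] = benjamini_hochberg(pvals[mask])
    significant = np.where(mask, padj < alpha, False).astype(bool)
    direction = np.where(log2fc > 0, "hyper", np.where(log2fc < 0, "hypo", "unchanged"))
    return pd.DataFrame(
        {
            f"mfpkm_{conds[0]}": m1,
            f"mfpkm_{conds[1]}": m2,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "significant": significant,
            "direction": direction,
            "tested": mask,
        },
        index=ip_counts.index,
    )


@dataclass(frozen=True)
class PeakFeatureOverlap:
    peak_id: str
    feature_id: str
    overlap_bp: int
    relation: str  # within-exon | spans-boundary | flanking-1kb


def overlap_peaks_features(
    peaks: pd.DataFrame,
    features: pd.DataFrame,
    flank: int = 1000,
) -> pd.DataFrame:
    """Half-open interval overlap between peaks and features.

    Both frames need chrom/start/end columns and ids as index. Relations:
    ``within-exon`` (peak contained in the feature), ``spans-boundary``
    (partial overlap), ``flanking-1kb`` (no overlap, gap <= ``flank``).
    Intervals touching only at a shared boundary have zero overlap and
    fall under the flank rule.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for fid, row in features.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]) - flank, int(row["end"]) + flank, fid
        )
    rows = []
    for pid, row in peaks.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        ps, pe = int(row["start"]), int(row["end"])
        for hit in sorted(tree.overlap(ps, pe), key=lambda h: (h.begin, str(h.data))):
            fs, fe = hit.begin + flank, hit.end - flank
            ov = min(pe, fe) - max(ps, fs)
            if ov > 0:
                relation = "within-exon" if (ps >= fs and pe <= fe) else "spans-boundary"
                rows.append((pid, hit.data, ov, relation))
            else:
                gap = max(fs - pe, ps - fe)
                if gap <= flank:
                    rows.append((pid, hit.data, 0, "flanking-1kb"))
    return pd.DataFrame(rows, columns=["peak_id", "feature_id", "overlap_bp", "relation"])
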