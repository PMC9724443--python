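"""Integration of m6A methylation with alternative splicing.

This module joins the splicing and methylation results: the fraction of
m6A-modified vs unmodified genes carrying AS events, the AS-count
quartile grouping of modified genes against their m6A enrichment change,
the four-quadrant SE-DMAS classification (delta-PSI direction x m6A
direction for skipped exons carrying a differential peak on the cassette
exon), the intersection with a methyltransferase-knockdown DAS set, the
RRACH consensus-motif scan, and the RT-PCR band-intensity inclusion
formula used for wet-lab validation.
"""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import round_percentage

logger = logging.getLogger(__name__)

QUADRANTS = (
    ("increased", "hyper"),
    ("increased", "hypo"),
    ("decreased", "hyper"),
    ("decreased", "hypo"),
)


def as_fraction_by_modification(m6a_flags: pd.Series, as_flags: pd.Series) -> dict:
    """Fraction of genes with >=1 AS event among modified vs unmodified genes.

    Both inputs are boolean Series over the same expressed-gene index.
    Raises on an empty class (the ratio would be undefined).
    """
    m6a_flags, as_flags = m6a_flags.align(as_flags, join="inner")
    modified = as_flags[m6a_flags.astype(bool)]
    unmodified = as_flags[~m6a_flags.astype(bool)]
    if len(modified) == 0 or len(unmodified) == 0:
        raise ValueError("empty modified or unmodified gene class")
    f_mod = float(modified.mean())
    f_unmod = float(unmodified.mean())
    return {
        "n_modified": int(len(modified)),
        "n_unmodified": int(len(unmodified)),
        "fraction_modified": f_mod,
        "fraction_unmodified": f_unmod,
        "ratio": f_mod / f_unmod if f_unmod > 0 else float("inf"),
    }


def group_by_as_counts(as_counts: pd.Series) -> pd.DataFrame:
    """Quartile grouping of m6A-modified genes by their AS event count.

    high: count >= Q3; low: count <= Q1; medium: strictly between.
    Quartiles use linear interpolation (numpy default, type 7). When
    Q1 == Q3 a gene satisfying both boundary rules goes to ``high``
    (precedence high, then low; logged). Requires >= 4 genes.
    """
    if len(as_counts) < 4:
        raise ValueError("need at least 4 genes for quartile grouping")
    counts = as_counts.astype(float)
    q1, q3 = np.quantile(counts.to_numpy(), [0.25, 0.75])
    if q1 == q3:
        logger.warning("degenerate quartiles (Q1 == Q3 == %s): high takes precedence", q1)
    group = np.where(counts >= q3, "high", np.where(counts <= q1, "low", "medium"))
    return pd.DataFrame({"as_count": as_counts, "group": group, "q1": q1, "q3": q3})


def compare_group_enrichment(
    groups: pd.DataFrame, mfpkm_log2fc: pd.Series
) -> dict:
    """One-sided Mann-Whitney tests of m6A change ordered high > medium > low."""
    merged = groups.join(mfpkm_log2fc.rename("log2fc"), how="inner").dropna(subset=["log2fc"])
    vals = {g: merged.loc[merged["group"] == g, "log2fc"].to_numpy() for g in ("high", "medium", "low")}
    out = {f"mean_log2fc_{g}": float(v.mean()) if len(v) else float("nan") for g, v in vals.items()}
    for top, bottom in (("high", "medium"), ("medium", "low"), ("high", "low")):
        if len(vals[top]) and len(vals[bottom]):
            p = stats.mannwhitneyu(vals[top], vals[bottom], alternative="greater").pvalue
        else:
            p = float("nan")
        out[f"p_{top}_gt_{bottom}"] = float(p)
    return out


def classify_sedmas(
    das_results: pd.DataFrame,
    dm_peaks: pd.DataFrame,
    overlaps: pd.DataFrame,
    das_alpha: float = 0.05,
    peak_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Four-quadrant classification of skipped exons with differential m6A.

    Joins SE-type DAS events (FDR < ``das_alpha``) with differential
    peaks (padj < ``peak_alpha``) overlapping the cassette exon; when
    several significant peaks overlap one exon the largest overlap wins,
    ties resolved by leftmost peak start. Quadrant = PSI direction
    (increased/decreased) x m6A direction (hyper/hypo).

    Parameters
    ----------
    das_results : indexed by event_id with columns gene_id, event_type,
        delta_psi, padj, das, direction.
    dm_peaks : indexed by peak_id with columns start, log2fc, padj,
        significant, direction.
    overlaps : peak_id, feature_id (= event_id of the cassette exon),
        overlap_bp rows; only within/spans relations should be passed.

    Returns (records, summary) where summary holds the 2x2 quadrant
    counts, the record total and the gene-level roll-up.
    """
    se_das = das_results[(das_results["event_type"] == "SE") & das_results["das"]]
    sig_peaks = dm_peaks[dm_peaks["significant"]]
    ov = overlaps[
        (overlaps["overlap_bp"] >= 1)
        & overlaps["peak_id"].isin(sig_peaks.index)
        & overlaps["feature_id"].isin(se_das.index)
    ].copy()
    ov["peak_start"] = sig_peaks["start"].reindex(ov["peak_id"]).to_numpy()
    ov = ov.sort_values(
        ["feature_id", "overlap_bp", "peak_start"], ascending=[True, False, True]
    ).drop_duplicates("feature_id", keep="first")

    rows = []
    for _, r in ov.iterrows():
        ev = se_das.loc[r["feature_id"]]
        pk = sig_peaks.loc[r["peak_id"]]
        rows.append(
            {
                "event_id": r["feature_id"],
                "gene_id": ev["gene_id"],
                "delta_psi": float(ev["delta_psi"]),
                "das_fdr": float(ev["padj"]),
                "peak_id": r["peak_id"],
                "m6a_log2fc": float(pk["log2fc"]),
                "m6a_padj": float(pk["padj"]),
                "overlap_bp": int(r["overlap_bp"]),
                "psi_direction": ev["direction"],
                "m6a_direction": pk["direction"],
                "quadrant": f"{ev['direction']}/{pk['direction']}",
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene_id", "delta_psi", "das_fdr", "peak_id",
            "m6a_log2fc", "m6a_padj", "overlap_bp", "psi_direction",
            "m6a_direction", "quadrant",
        ],
    ).set_index("event_id")
    quad_counts = {
        f"{p}/{m}": int(((records["psi_direction"] == p) & (records["m6a_direction"] == m)).sum())
        for p, m in QUADRANTS
    }
    summary = {
        "quadrants": quad_counts,
        "n_records": int(len(records)),
        "n_increased": quad_counts["increased/hyper"] + quad_counts["increased/hypo"],
        "n_decreased": quad_counts["decreased/hyper"] + quad_counts["decreased/hypo"],
        "n_genes": int(records["gene_id"].nunique()),
    }
    return records, summary


def _event_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["gene_id"].astype(str)
        + "|" + df["cassette_start"].astype(int).astype(str)
        + "|" + df["cassette_end"].astype(int).astype(str)
        + "|" + df["strand"].astype(str)
    )


def intersect_knockdown(
    tissue_sedmas: pd.DataFrame, knockdown_das: pd.DataFrame
) -> dict:
    """Shared skipped-exon events between the tissue SE-DMAS set and a
    knockdown SE-DAS set.

    Event identity is (gene_id, cassette exon coordinates, strand); both
    inputs need gene_id, cassette_start, cassette_end, strand columns in
    the same 0-based half-open convention. If nothing matches but a
    one-base coordinate shift would, a loud warning flags a likely
    1-based/0-based convention mismatch. The shared fraction of the
    tissue set is reported as a one-decimal percentage.
    """
    t_keys = set(_event_key(tissue_sedmas))
    k_keys = set(_event_key(knockdown_das))
    shared = sorted(t_keys & k_keys)
    if not shared and len(t_keys) and len(k_keys):
        for shift in (-1, 1):
            kd = knockdown_das.copy()
            kd["cassette_start"] = kd["cassette_start"] + shift
            kd["cassette_end"] = kd["cassette_end"] + shift
            if t_keys & set(_event_key(kd)):
                warnings.warn(
                    "intersect_knockdown: zero matches, but shifting knockdown "
                    f"coordinates by {shift} produces matches - likely a "
                    "1-based/0-based coordinate convention mismatch",
                    stacklevel=2,
                )
                break
    return {
        "n_tissue": len(t_keys),
        "n_knockdown": len(k_keys),
        "n_shared": len(shared),
        "shared": shared,
        "shared_percent_of_tissue": round_percentage(len(shared), len(t_keys), 1)
        if t_keys
        else float("nan"),
    }


_RRACH = re.compile(r"(?=[AG][AG]AC[ACT])")
_VALID = re.compile(r"^[ACGTUN]*$")
_COMP = str.maketrans("ACGTN", "TGCAN")


def rrach_scan(sequence: str, reverse_complement: bool = False) -> list[int]:
    """Positions of RRACH (R = A/G, H = A/C/U) matches, overlaps included.

    N never matches. With ``reverse_complement`` the scan runs on the
    reverse complement (positions refer to the transformed sequence).
    DNA and RNA alphabets are both accepted (U is treated as T).
    """
    seq = sequence.upper().replace("U", "T")
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTUN"))
        raise ValueError(f"invalid sequence characters: {bad}")
    if reverse_complement:
        seq = seq.translate(_COMP)[::-1]
    return [m.start() for m in _RRACH.finditer(seq)]


def rtpcr_inclusion(upper_intensity: float, lower_intensity: float) -> float:
    """Gel-band inclusion level: upper / (upper + lower).

    The upper band is the exon-inclusion product, the lower band the
    exon-skipping product.
    """
    if upper_intensity < 0 or lower_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = upper_intensity + lower_intensity
    if total == 0:
        raise ValueError("both band intensities are zero")
    return upper_intensity / total
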