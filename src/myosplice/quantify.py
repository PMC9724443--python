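"""Expression and inclusion-level quantification.

FPKM (fragments per kilobase of exon per million fragments) normalises raw
gene counts by gene length and library size; genes with FPKM >= 0.5 in at
least one library are called expressed. PSI (percent spliced in, psi) is
the fraction of transcripts including the alternative exon, estimated from
length-normalised inclusion and skipping junction counts:

    psi = (I / l_I) / (I / l_I + S / l_S)

where l_I and l_S are the effective lengths of the inclusion and skipping
junction forms. Events with fewer than ``min_total`` supporting reads in a
sample are reported missing (NaN) for that sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count / (length/1e3) / (library_size/1e6).

    Parameters
    ----------
    counts : gene x sample raw fragment counts (non-negative).
    lengths : effective gene length in bp, indexed like ``counts``.
    library_sizes : per-sample totals; defaults to column sums of ``counts``
        (total counted fragments).
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    mill = library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / kb / mill,
        index=counts.index,
        columns=counts.columns,
    )


def filter_expressed(
    fpkm: pd.DataFrame, threshold: float = 0.5, min_libraries: int = 1
) -> pd.Index:
    """Genes with FPKM >= threshold in at least ``min_libraries`` samples.

    The comparison is inclusive: a gene whose maximum FPKM is exactly the
    threshold is kept.
    """
    keep = (fpkm >= threshold).sum(axis=1) >= min_libraries
    return fpkm.index[keep]


def estimate_psi(I, S, l_I, l_S, min_total: int = 10):
    """Length-normalised percent spliced in; NaN below the coverage floor.

    Accepts scalars or aligned arrays. ``l_I``/``l_S`` are the effective
    lengths of the inclusion and skipping forms; PSI is invariant to
    scaling both by a common factor.
    """
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    l_I = np.asarray(l_I, dtype=float)
    l_S = np.asarray(l_S, dtype=float)
    if (l_I <= 0).any() or (l_S <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (I < 0).any() or (S < 0).any():
        raise ValueError("junction counts must be non-negative")
    ni = I / l_I
    ns = S / l_S
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = ni / (ni + ns)
    psi = np.where(I + S < min_total, np.nan, psi)
    if psi.ndim == 0:
        return float(psi)
    return psi


def psi_matrix(
    event_counts: pd.DataFrame,
    event_lengths: pd.DataFrame,
    min_total: int = 10,
) -> pd.DataFrame:
    """Pivot a long event-count table into an event x sample PSI matrix.

    ``event_counts`` columns: event_id, sample_id, inclusion_count,
    skipping_count. ``event_lengths`` columns: inclusion_length,
    skipping_length, indexed by event_id. Missing PSI encoded as NaN.
    """
    I = event_counts.pivot(index="event_id", columns="sample_id", values="inclusion_count")
    S = event_counts.pivot(index="event_id", columns="sample_id", values="skipping_count")
    l_I = event_lengths["inclusion_length"].reindex(I.index)
    l_S = event_lengths["skipping_length"].reindex(I.index)
    vals = estimate_psi(
        I.to_numpy(), S.to_numpy(), l_I.to_numpy()[:, None], l_S.to_numpy()[:, None],
        min_total=min_total,
    )
    return pd.DataFrame(vals, index=I.index, columns=I.columns)
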