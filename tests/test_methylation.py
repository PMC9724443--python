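import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myosplice.methylation import (
    _one_sided_enrichment_p,
    call_peaks,
    compute_mfpkm,
    overlap_peaks_features,
)
from myosplice.methylation import test_differential_methylation as dm_test

from oracles import brute_overlaps

SAMPLES = ["EDL_1", "EDL_2", "EDL_3", "SOL_1", "SOL_2", "SOL_3"]
DESIGN = pd.Series({s: s.rsplit("_", 1)[0] for s in SAMPLES})


def _bins(n, chrom="1", width=50):
    idx = [f"b{i}" for i in range(n)]
    return pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n) * width,
         "end": (np.arange(n) + 1) * width, "gene_id": "g"},
        index=pd.Index(idx, name="bin_id"),
    )


def test_hypergeom_tail_matches_fisher_exact():
    rng = np.random.default_rng(1)
    for _ in range(30):
        a, b, c, d = rng.integers(0, 60, size=4)
        p_fast = _one_sided_enrichment_p(
            np.array([a]), a + b, np.array([c]), c + d
        )[0]
        p_fisher = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert p_fast == pytest.approx(p_fisher, rel=1e-9)


def test_no_peaks_when_ip_equals_input():
    bins = _bins(20)
    counts = pd.DataFrame(
        np.full((20, 6), 40), index=bins.index, columns=SAMPLES
    )
    peaks, _, _ = call_peaks(bins, counts, counts.copy(), DESIGN)
    assert len(peaks) == 0


def test_adjacent_significant_bins_merge_into_one_peak():
    bins = _bins(30)
    inp = pd.DataFrame(np.full((30, 6), 50), index=bins.index, columns=SAMPLES)
    ip = inp.copy()
    ip.iloc[10:12] = 600  # two adjacent strongly enriched bins
    peaks, peak_ip, peak_input = call_peaks(bins, ip, inp, DESIGN)
    assert len(peaks) == 1
    peak = peaks.iloc[0]
    assert (peak["start"], peak["end"]) == (500, 600)
    assert peak_ip.iloc[0].sum() == 600 * 12
    assert len(peak_ip) == len(peak_input) == 1


def test_peak_coordinates_invariant_to_condition_swap():
    rng = np.random.default_rng(5)
    bins = _bins(40)
    inp = pd.DataFrame(rng.poisson(60, (40, 6)), index=bins.index, columns=SAMPLES)
    ip = pd.DataFrame(rng.poisson(60, (40, 6)), index=bins.index, columns=SAMPLES)
    ip.iloc[5:8] += 500
    swapped = DESIGN.map({"EDL": "SOL", "SOL": "EDL"})
    p1, _, _ = call_peaks(bins, ip, inp, DESIGN)
    p2, _, _ = call_peaks(bins, ip, inp, swapped)
    assert list(p1["start"]) == list(p2["start"]) and list(p1["end"]) == list(p2["end"])


def test_mfpkm_identity_mean_and_exclusion_rules():
    ip = pd.DataFrame([[10, 10, 10, 0, 0, 0]], columns=SAMPLES, index=["r"])
    inp = ip.copy()
    libs = pd.Series(1e6, index=SAMPLES)
    m = compute_mfpkm(ip, inp, DESIGN, libs, libs)
    assert m.loc["r", "EDL"] == pytest.approx(1.0)

    # ratios {2, 4, 6} average to 4
    ip2 = pd.DataFrame([[20, 40, 60, 1, 1, 1]], columns=SAMPLES, index=["r"])
    inp2 = pd.DataFrame([[10, 10, 10, 1, 1, 1]], columns=SAMPLES, index=["r"])
    m2 = compute_mfpkm(ip2, inp2, DESIGN, libs, libs)
    assert m2.loc["r", "EDL"] == pytest.approx(4.0)

    # a zero-input replicate is excluded, not divided by zero
    inp3 = pd.DataFrame([[10, 0, 10, 1, 1, 1]], columns=SAMPLES, index=["r"])
    m3 = compute_mfpkm(ip2, inp3, DESIGN, libs, libs)
    assert m3.loc["r", "EDL"] == pytest.approx((2 + 6) / 2)


def test_mfpkm_invariant_to_common_library_scaling():
    rng = np.random.default_rng(2)
    ip = pd.DataFrame(rng.poisson(80, (5, 6)), columns=SAMPLES)
    inp = pd.DataFrame(rng.poisson(40, (5, 6)) + 1, columns=SAMPLES)
    libs = pd.Series(rng.uniform(1e6, 2e6, 6), index=SAMPLES)
    m1 = compute_mfpkm(ip, inp, DESIGN, libs, libs)
    m2 = compute_mfpkm(ip, inp, DESIGN, libs * 3.7, libs * 3.7)
    pd.testing.assert_frame_equal(m1, m2)


def test_dm_null_and_condition_swap_symmetry():
    ip = pd.DataFrame([[100, 110, 90, 100, 95, 105]], columns=SAMPLES, index=["r"])
    inp = pd.DataFrame([[50, 55, 45, 50, 48, 52]], columns=SAMPLES, index=["r"])
    libs = pd.Series(1e6, index=SAMPLES)
    res = dm_test(ip, inp, DESIGN, ip_library_sizes=libs, input_library_sizes=libs)
    assert abs(res["log2fc"].iloc[0]) < 0.2
    assert not res["significant"].iloc[0]

    ip2 = ip.copy()
    ip2.loc["r", ["SOL_1", "SOL_2", "SOL_3"]] = 500
    swapped = DESIGN.map({"EDL": "SOL", "SOL": "EDL"})
    a = dm_test(ip2, inp, DESIGN, ip_library_sizes=libs, input_library_sizes=libs)
    b = dm_test(ip2, inp, swapped, ip_library_sizes=libs, input_library_sizes=libs)
    assert a["log2fc"].iloc[0] == pytest.approx(-b["log2fc"].iloc[0])
    assert a["pvalue"].iloc[0] == pytest.approx(b["pvalue"].iloc[0])


def _frame(d):
    return pd.DataFrame(
        {"chrom": [v[0] for v in d.values()],
         "start": [v[1] for v in d.values()],
         "end": [v[2] for v in d.values()]},
        index=list(d),
    )


def test_overlap_relations_hand_cases():
    peaks = _frame({"p1": ("1", 100, 200), "p2": ("1", 0, 50), "p3": ("1", 160, 180)})
    feats = _frame({"f1": ("1", 150, 250), "f2": ("1", 200, 300), "f3": ("1", 600, 700)})
    out = overlap_peaks_features(peaks, feats, flank=1000)
    rows = {(r["peak_id"], r["feature_id"]): (r["overlap_bp"], r["relation"])
            for _, r in out.iterrows()}
    assert rows[("p1", "f1")] == (50, "spans-boundary")
    assert rows[("p1", "f2")][0] == 0 and rows[("p1", "f2")][1] == "flanking-1kb"
    assert rows[("p2", "f3")] == (0, "flanking-1kb")
    assert rows[("p3", "f1")] == (20, "within-exon")


def test_overlap_rejects_negative_flank():
    with pytest.raises(ValueError):
        overlap_peaks_features(_frame({}), _frame({}), flank=-1)


def test_overlap_matches_all_pairs_oracle():
    rng = np.random.default_rng(9)
    peaks = {
        f"p{i}": ("1", int(s), int(s + rng.integers(10, 300)))
        for i, s in enumerate(rng.integers(0, 5000, 80))
    }
    feats = {
        f"f{i}": ("1", int(s), int(s + rng.integers(10, 300)))
        for i, s in enumerate(rng.integers(0, 5000, 80))
    }
    got = overlap_peaks_features(_frame(peaks), _frame(feats), flank=200)
    got_map = {(r["peak_id"], r["feature_id"]): (r["overlap_bp"], r["relation"])
               for _, r in got.iterrows()}
    assert got_map == brute_overlaps(peaks, feats, 200)
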