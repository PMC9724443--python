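import numpy as np
import pandas as pd
import pytest

from myosplice.integration import (
    as_fraction_by_modification,
    classify_sedmas,
    compare_group_enrichment,
    group_by_as_counts,
    intersect_knockdown,
    rrach_scan,
    rtpcr_inclusion,
)

from oracles import brute_rrach_positions


def test_as_fraction_hand_arithmetic():
    idx = [f"g{i}" for i in range(20)]
    m6a = pd.Series([True] * 10 + [False] * 10, index=idx)
    has_as = pd.Series([True] * 8 + [False] * 2 + [True] * 4 + [False] * 6, index=idx)
    out = as_fraction_by_modification(m6a, has_as)
    assert out["fraction_modified"] == pytest.approx(0.8)
    assert out["fraction_unmodified"] == pytest.approx(0.4)
    assert out["ratio"] == pytest.approx(2.0)


def test_as_fraction_rejects_empty_class():
    idx = ["a", "b"]
    with pytest.raises(ValueError):
        as_fraction_by_modification(
            pd.Series([True, True], index=idx), pd.Series([True, False], index=idx)
        )


def test_as_fraction_null_ratio_near_one():
    rng = np.random.default_rng(0)
    idx = [f"g{i}" for i in range(4000)]
    m6a = pd.Series(rng.random(4000) < 0.5, index=idx)
    has_as = pd.Series(rng.random(4000) < 0.6, index=idx)
    out = as_fraction_by_modification(m6a, has_as)
    assert out["ratio"] == pytest.approx(1.0, abs=0.1)


def test_quartile_grouping_type7_hand_values():
    counts = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=[f"g{i}" for i in range(8)])
    groups = group_by_as_counts(counts)
    assert groups["q1"].iloc[0] == pytest.approx(2.75)
    assert groups["q3"].iloc[0] == pytest.approx(6.25)
    by = groups.groupby("group").groups
    assert sorted(counts[by["low"]]) == [1, 2]
    assert sorted(counts[by["high"]]) == [7, 8]
    assert sorted(counts[by["medium"]]) == [3, 4, 5, 6]


def test_quartile_grouping_degenerate_still_partitions():
    counts = pd.Series([3] * 6, index=[f"g{i}" for i in range(6)])
    groups = group_by_as_counts(counts)
    assert (groups["group"] == "high").all()  # high takes precedence over low


def test_quartile_grouping_needs_four_genes():
    with pytest.raises(ValueError):
        group_by_as_counts(pd.Series([1, 2, 3]))


def test_group_enrichment_recovers_planted_ordering():
    """With m6A change coupled positively to AS count, mean log2FC(MFPKM)
    orders high > medium > low with one-sided significance."""
    rng = np.random.default_rng(3)
    n = 500
    counts = pd.Series(rng.poisson(4.0, n) + 1, index=[f"g{i}" for i in range(n)])
    lfc = pd.Series(0.3 * counts + rng.normal(0, 0.5, n), index=counts.index)
    groups = group_by_as_counts(counts)
    out = compare_group_enrichment(groups, lfc)
    assert out["mean_log2fc_high"] > out["mean_log2fc_medium"] > out["mean_log2fc_low"]
    assert out["p_high_gt_medium"] < 0.05
    assert out["p_medium_gt_low"] < 0.05


def _sedmas_inputs(rows):
    das = pd.DataFrame(
        [
            {"event_id": f"e{i}", "gene_id": f"g{i}", "event_type": "SE",
             "delta_psi": d, "padj": 0.001, "das": True,
             "direction": "increased" if d > 0 else "decreased"}
            for i, (d, _) in enumerate(rows)
        ]
    ).set_index("event_id")
    peaks = pd.DataFrame(
        [
            {"peak_id": f"p{i}", "start": 100 * i, "log2fc": m, "padj": 0.001,
             "significant": True, "direction": "hyper" if m > 0 else "hypo"}
            for i, (_, m) in enumerate(rows)
        ]
    ).set_index("peak_id")
    overlaps = pd.DataFrame(
        {"peak_id": [f"p{i}" for i in range(len(rows))],
         "feature_id": [f"e{i}" for i in range(len(rows))],
         "overlap_bp": 100, "relation": "within-exon"}
    )
    return das, peaks, overlaps


def test_sedmas_sign_rule_and_filters():
    das, peaks, overlaps = _sedmas_inputs([(0.3, 1.5), (-0.2, -2.0)])
    peaks.loc["p1", ["significant", "padj"]] = [False, 0.4]
    records, summary = classify_sedmas(das, peaks, overlaps)
    assert list(records.index) == ["e0"]
    assert records.loc["e0", "quadrant"] == "increased/hyper"
    assert summary["n_records"] == 1 and summary["quadrants"]["increased/hyper"] == 1


def test_sedmas_largest_overlap_wins_ties_leftmost():
    das, peaks, overlaps = _sedmas_inputs([(0.3, 1.5)])
    peaks = pd.concat(
        [peaks, pd.DataFrame(
            [{"start": 5, "log2fc": -1.0, "padj": 0.001,
              "significant": True, "direction": "hypo"},
             {"start": 1, "log2fc": -1.0, "padj": 0.001,
              "significant": True, "direction": "hypo"}],
            index=["pB", "pA"])]
    )
    overlaps = pd.DataFrame(
        {"peak_id": ["p0", "pB", "pA"], "feature_id": ["e0"] * 3,
         "overlap_bp": [40, 80, 80], "relation": "within-exon"}
    )
    records, _ = classify_sedmas(das, peaks, overlaps)
    assert records.loc["e0", "peak_id"] == "pA"  # 80bp tie, start 1 < 5


def _kd_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "cassette_start", "cassette_end", "strand"]
    )


def test_knockdown_intersection_counts_and_percent():
    tissue = _kd_frame([("g1", 100, 200, "+"), ("g2", 300, 400, "-")])
    kd_same = _kd_frame([("g1", 100, 200, "+"), ("g3", 1, 50, "+")])
    out = intersect_knockdown(tissue, kd_same)
    assert out["n_shared"] == 1
    assert out["shared_percent_of_tissue"] == 50.0
    disjoint = intersect_knockdown(tissue, _kd_frame([("g9", 5, 6, "+")]))
    assert disjoint["n_shared"] == 0
    identical = intersect_knockdown(tissue, tissue)
    assert identical["n_shared"] == 2 and identical["shared_percent_of_tissue"] == 100.0


def test_knockdown_off_by_one_triggers_convention_warning():
    tissue = _kd_frame([("g1", 100, 200, "+")])
    shifted = _kd_frame([("g1", 101, 201, "+")])
    with pytest.warns(UserWarning, match="convention"):
        out = intersect_knockdown(tissue, shifted)
    assert out["n_shared"] == 0


def test_rrach_hand_cases():
    assert rrach_scan("GGACU") == [0]
    assert rrach_scan("CCCCC") == []
    assert rrach_scan("GGACAGACU") == [0, 4]  # overlapping matches both count
    assert rrach_scan("GGNCU") == []  # N never matches
    assert rrach_scan("ggacu") == [0]


def test_rrach_rejects_invalid_characters():
    with pytest.raises(ValueError, match="invalid"):
        rrach_scan("GGAXU")


def test_rrach_reverse_complement_scan():
    # reverse complement of AGTCC is GGACT, one canonical site
    assert rrach_scan("AGTCC", reverse_complement=True) == [0]


def test_rrach_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    alphabet = np.array(list("ACGTN"))
    for _ in range(200):
        seq = "".join(rng.choice(alphabet, size=300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        assert rrach_scan(seq) == brute_rrach_positions(seq)


def test_rtpcr_inclusion_formula():
    assert rtpcr_inclusion(1, 0) == 1.0
    assert rtpcr_inclusion(0, 1) == 0.0
    assert rtpcr_inclusion(30, 70) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        rtpcr_inclusion(0, 0)
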