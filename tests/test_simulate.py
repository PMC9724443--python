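import numpy as np
import pandas as pd
import pytest

from myosplice.annotation import classify_as_events, count_events_per_gene
from myosplice.quantify import estimate_psi
from myosplice.simulate import (
    CONDITIONS,
    SimulationConfig,
    event_table,
    generate_gene_models,
    simulate_dataset,
    simulate_event_counts,
    simulate_expression,
    simulate_knockdown_das,
    simulate_merip,
    simulate_sf_coupling,
    tile_gene_bins,
)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationConfig(n_replicates=1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(planted_dpsi=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(nb_dispersion=-0.1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_transcripts_per_gene=(3, 1)).validate()


def test_classifier_recovers_constructed_truth_exactly():
    genes, truth = generate_gene_models(SimulationConfig(n_genes=100, seed=1))
    recovered = {ev.event_id for g in genes for ev in classify_as_events(g)}
    assert recovered == {ev.event_id for ev in truth}


def test_truth_ids_resolve_and_das_subset_of_se(small_dataset):
    ds = small_dataset
    catalogue = set(ds.events.index)
    assert ds.truth.das_events <= catalogue
    se_ids = set(ds.events.index[ds.events["event_type"] == "SE"])
    assert ds.truth.das_events <= se_ids
    assert set(ds.truth.true_psi.index) == catalogue
    for targets in ds.truth.sf_targets.values():
        assert set(targets) <= ds.truth.das_events
    linked = ds.truth.dm_peaks["event_id"].dropna()
    assert set(linked) <= ds.truth.das_events


def test_same_seed_gives_identical_outputs_different_seed_does_not():
    a = simulate_dataset(SimulationConfig(n_genes=50, seed=9))
    b = simulate_dataset(SimulationConfig(n_genes=50, seed=9))
    c = simulate_dataset(SimulationConfig(n_genes=50, seed=10))
    pd.testing.assert_frame_equal(a.gene_counts, b.gene_counts)
    pd.testing.assert_frame_equal(a.event_counts, b.event_counts)
    pd.testing.assert_frame_equal(a.ip_counts, b.ip_counts)
    assert not a.gene_counts.equals(c.gene_counts)


def test_event_counts_zero_depth_and_boundary_psi():
    config = SimulationConfig(n_genes=10, seed=0, depth_per_event=0.0)
    genes, truth = generate_gene_models(config)
    events = event_table(truth, config)
    psi = pd.DataFrame(1.0, index=events.index, columns=config.samples)
    zero = simulate_event_counts(events, psi * 0.5,
                                 SimulationConfig(depth_per_event=0.0, seed=0))
    assert (zero[["inclusion_count", "skipping_count"]] == 0).all().all()

    full = simulate_event_counts(events, psi, SimulationConfig(depth_per_event=50, seed=0))
    assert (full["skipping_count"] == 0).all()


def test_psi_estimator_unbiased_for_planted_psi():
    """At depth 2000 x 3 replicates the mean estimated PSI sits within
    the binomial standard error band of the planted 0.6."""
    config = SimulationConfig(depth_per_event=2000, seed=2, psi_replicate_sd=0.0)
    genes, truth = generate_gene_models(SimulationConfig(n_genes=30, seed=2))
    events = event_table(truth, config)
    psi = pd.DataFrame(0.6, index=events.index, columns=config.samples)
    counts = simulate_event_counts(events, psi, config)
    est = estimate_psi(
        counts["inclusion_count"].to_numpy(),
        counts["skipping_count"].to_numpy(),
        events["inclusion_length"].reindex(counts["event_id"]).to_numpy(),
        events["skipping_length"].reindex(counts["event_id"]).to_numpy(),
    )
    assert np.nanmean(est) == pytest.approx(0.6, abs=0.03)


def test_expression_poisson_limit_and_planted_fold_change():
    lengths = pd.Series(1000, index=[f"g{i}" for i in range(1500)])
    cfg = SimulationConfig(nb_dispersion=0.0, de_fraction=0.0, seed=4)
    counts, libfac, _, _ = simulate_expression(lengths, cfg, rng=np.random.default_rng(4))
    norm = counts / libfac  # remove the planted library-size variation
    disp_index = norm.var(axis=1, ddof=1) / norm.mean(axis=1)
    # Poisson limit: variance equals mean, so the dispersion index is ~1
    assert disp_index.mean() == pytest.approx(1.0, abs=0.15)

    cfg2 = SimulationConfig(nb_dispersion=0.02, de_fraction=1.0, de_log2fc=2.0,
                            mean_expression=1000, seed=5)
    counts2, _, de_genes, de_signs = simulate_expression(
        lengths, cfg2, rng=np.random.default_rng(5)
    )
    up = [g for g in de_genes if de_signs[g] > 0]
    edl = counts2.loc[up, [f"{CONDITIONS[0]}_{i+1}" for i in range(3)]].mean(axis=1)
    sol = counts2.loc[up, [f"{CONDITIONS[1]}_{i+1}" for i in range(3)]].mean(axis=1)
    assert (sol / edl).median() == pytest.approx(4.0, abs=0.5)


def test_expression_rejects_negative_dispersion():
    with pytest.raises(ValueError):
        simulate_expression(
            pd.Series(1000, index=["g1"]), SimulationConfig(nb_dispersion=-1.0)
        )


def test_merip_background_ratio_and_bin_guard(small_dataset):
    cfg = SimulationConfig(n_genes=40, seed=7, m6a_gene_fraction=0.0, das_fraction=0.0)
    ds = simulate_dataset(cfg)
    ratio = ds.ip_counts.sum(axis=1) / ds.input_counts.sum(axis=1).replace(0, np.nan)
    assert float(ratio.median()) == pytest.approx(1.0, abs=0.1)

    bins = tile_gene_bins(ds.genes[:2], 50)
    with pytest.raises(ValueError, match="outside"):
        simulate_merip(
            bins, ds.truth.dm_peaks, cfg,
            gene_factors=pd.Series(1.0, index=["not_a_gene"]),
        )


def test_sf_coupling_signs_and_collision_guard():
    cfg = SimulationConfig(sf_coupling_noise=0.0)
    psi = pd.DataFrame(
        np.random.default_rng(1).uniform(0.1, 0.9, (2, 6)),
        index=["eA", "eB"], columns=cfg.samples,
    )
    expr = simulate_sf_coupling(
        ["SF_pos", "SF_neg"], {"SF_pos": ["eA"], "SF_neg": ["eB"]}, psi, cfg,
        rng=np.random.default_rng(2),
    )
    from myosplice.network import spearman_rho

    assert spearman_rho(expr.loc["SF_pos"], psi.loc["eA"])[0] == pytest.approx(1.0)
    assert spearman_rho(expr.loc["SF_neg"], psi.loc["eB"])[0] == pytest.approx(-1.0)

    with pytest.raises(ValueError, match="collide"):
        simulate_sf_coupling(["gX"], {}, psi, cfg, existing_gene_ids=["gX"])


def test_knockdown_table_shares_planted_subset(small_dataset):
    kd, shared = simulate_knockdown_das(small_dataset)
    assert shared <= small_dataset.truth.das_events
    assert set(kd.index) >= shared
    assert {"gene_id", "cassette_start", "cassette_end", "strand"} <= set(kd.columns)


def test_catalogue_contains_multi_event_genes(small_dataset):
    summary = count_events_per_gene(small_dataset.truth.events)
    assert len(summary.multi_event_genes) > 0
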