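"""Generator contracts: planting fidelity, determinism, round-trips."""

import numpy as np
import pandas as pd
import pytest

from mcscreen import io
from mcscreen.conservation import (
    ABSENT,
    CONSERVED,
    HIGH_DIVERGENCE,
    MILD_DIVERGENCE,
    screen_proteome,
)
from mcscreen.expression_screen import filter_overexpressed
from mcscreen.synthetic_data import (
    ModuleSpec,
    SimulationConfig,
    simulate_clade_tables,
    simulate_de_experiments,
    simulate_network,
    simulate_profiles,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=10, module_specs=[ModuleSpec(20, {0})])
    with pytest.raises(ValueError):
        SimulationConfig(background_overexpr_prob=1.5)
    with pytest.raises(ValueError):
        ModuleSpec(5, {0}, activation_prob=2.0)
    with pytest.raises(ValueError):
        SimulationConfig(module_specs=[ModuleSpec(5, {99})], n_genes=10)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(n_genes=50, module_specs=[ModuleSpec(10, {0, 1}, 0.8)],
                           seed=4)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back == cfg


def test_certain_activation_plants_exact_profiles():
    cfg = SimulationConfig(
        n_genes=60, n_experiments=5,
        module_specs=[ModuleSpec(20, {1, 2, 3}, activation_prob=1.0)],
        background_overexpr_prob=0.0, seed=1,
    )
    tables, gt = simulate_de_experiments(cfg)
    sets = [filter_overexpressed(t) for t in tables]
    module = {g for g, m in gt.module_of.items() if m == "M1"}
    for i, s in enumerate(sets):
        assert (s == module) if i in {1, 2, 3} else (s == set())


def test_background_exceeds_thresholds_in_at_most_one_experiment():
    cfg = SimulationConfig(n_genes=200, n_experiments=8, module_specs=[],
                           background_overexpr_prob=0.5, seed=2)
    tables, gt = simulate_de_experiments(cfg)
    counts = {}
    for t in tables:
        for g in filter_overexpressed(t):
            counts[g] = counts.get(g, 0) + 1
    assert counts and max(counts.values()) == 1


def test_same_seed_reproduces_tables_byte_identically(tmp_path):
    cfg = SimulationConfig(n_genes=50, n_experiments=3, module_specs=[],
                           background_overexpr_prob=0.2, seed=9)
    paths = []
    for run in range(2):
        tables, _ = simulate_de_experiments(cfg)
        p = tmp_path / f"run{run}.tsv"
        io.write_experiment_table(tables[0].data, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_named_streams_are_independent():
    # changing the network seed path must not perturb the DE tables
    cfg = SimulationConfig(n_genes=30, n_experiments=3, module_specs=[],
                           community_sizes=[3, 4], seed=5)
    t1, _ = simulate_de_experiments(cfg)
    simulate_network(cfg)
    t2, _ = simulate_de_experiments(cfg)
    pd.testing.assert_frame_equal(t1[0].data, t2[0].data)


def test_clade_planting_recovered_exactly_by_classifier():
    cfg = SimulationConfig(n_genes=100, module_specs=[], planted_losses=20,
                           planted_high_div=10, planted_mild_div=15, seed=6)
    table, gt = simulate_clade_tables(cfg)
    calls, summary = screen_proteome(table)
    assert summary["counts"][ABSENT] == 20
    assert summary["counts"][HIGH_DIVERGENCE] == 10
    assert summary["counts"][MILD_DIVERGENCE] == 15
    assert summary["counts"][CONSERVED] == 55
    assert summary["flagged"] == 45
    for gene, category in zip(calls["gene"], calls["category"]):
        assert gt.conservation_of[gene] == category


def test_no_planting_means_all_conserved():
    cfg = SimulationConfig(n_genes=30, module_specs=[], planted_losses=0,
                           planted_high_div=0, planted_mild_div=0, seed=6)
    table, _ = simulate_clade_tables(cfg)
    _, summary = screen_proteome(table)
    assert summary["counts"][CONSERVED] == 30
    assert summary["flagged"] == 0


def test_clade_requires_two_species_per_side():
    cfg = SimulationConfig(n_genes=10, module_specs=[], n_focal_species=1,
                           planted_losses=0, planted_high_div=0,
                           planted_mild_div=0)
    with pytest.raises(ValueError):
        simulate_clade_tables(cfg)


def test_clade_table_round_trips_through_tsv(tmp_path):
    cfg = SimulationConfig(n_genes=20, module_specs=[], planted_losses=5,
                           planted_high_div=3, planted_mild_div=2, seed=8)
    table, _ = simulate_clade_tables(cfg)
    path = tmp_path / "clade.tsv"
    io.write_clade_table(table, path)
    back = io.read_clade_table(path)
    calls1, _ = screen_proteome(table)
    calls2, _ = screen_proteome(back)
    pd.testing.assert_frame_equal(calls1, calls2)


def test_profiles_have_requested_species_and_zero_noise_patterns():
    cfg = SimulationConfig(n_genes=20, module_specs=[], n_profile_species=711,
                           profile_patterns=[("ABSENT_FOCAL_CLADE", 10)],
                           profile_noise=0.0, seed=3)
    matrix, panel, gt = simulate_profiles(cfg)
    assert matrix.shape[1] == 711
    assert len(panel) == 711
    focal = panel.loc[panel["focal"], "species"]
    nonfocal_vert = panel.loc[(panel["subclade"] == "Vertebrata"), "species"]
    assert (matrix[focal] == 0).all().all()
    assert (matrix[nonfocal_vert] == 1).all().all()
    # identical patterns at zero noise are identical rows
    assert (matrix.iloc[0] == matrix.iloc[1]).all()


def test_network_planting_and_validation():
    cfg = SimulationConfig(module_specs=[], community_sizes=[10, 10],
                           intra_edge_prob=1.0, inter_edge_prob=0.0, seed=4)
    edges, gt = simulate_network(cfg)
    assert len(edges) == 2 * (10 * 9) // 2
    assert edges["score"].between(0, 1).all()
    again, _ = simulate_network(cfg)
    pd.testing.assert_frame_equal(edges, again)
    with pytest.raises(ValueError):
        simulate_network(SimulationConfig(module_specs=[], community_sizes=[2, 5]))
    with pytest.raises(ValueError):
        simulate_network(
            SimulationConfig(module_specs=[], community_sizes=[5, 5],
                             intra_edge_prob=0.1, inter_edge_prob=0.5)
        )


def test_fixture_shapes_and_planting(bundle):
    assert len(bundle.proteome) == 21044
    assert len(bundle.de_tables) == 10
    assert bundle.profile_presence.shape == (984, 711)
    assert len(bundle.target_list) == 122
    truth_cats = pd.Series(bundle.ground_truth.conservation_of)
    assert (truth_cats == ABSENT).sum() == 634
    assert (truth_cats == HIGH_DIVERGENCE).sum() == 104
    assert (truth_cats == MILD_DIVERGENCE).sum() == 623


def test_fixture_edge_list_round_trip(tmp_path, bundle):
    path = tmp_path / "edges.tsv"
    io.write_edge_list(bundle.network_edges, path)
    back = io.read_edge_list(path)
    pd.testing.assert_frame_equal(bundle.network_edges, back)
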