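"""Profile matrices, correlation distance and clade-pattern annotation."""

import numpy as np
import pandas as pd
import pytest

from mcscreen import io
from mcscreen.phylo_profiling import (
    ABSENT_FOCAL_CLADE,
    ABSENT_NONCILIATED,
    MAX_CORRELATION_DISTANCE,
    PRESENT_BROADLY,
    annotate_clusters,
    build_profile_matrix,
    cluster_profiles,
    correlation_distance,
    correlation_distance_matrix,
)
from mcscreen.synthetic_data import (
    SimulationConfig,
    build_species_panel,
    simulate_profiles,
)


def test_correlation_distance_worked_examples():
    assert correlation_distance([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(0.0)
    assert correlation_distance([1, 0, 1, 0], [0, 1, 0, 1]) == pytest.approx(2.0)
    assert correlation_distance([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1.0)


def test_correlation_distance_constant_vector_sentinel():
    assert correlation_distance([1, 1, 1], [1, 0, 1]) == MAX_CORRELATION_DISTANCE


def test_correlation_distance_validation():
    with pytest.raises(ValueError):
        correlation_distance([1, 0], [1, 0, 1])
    with pytest.raises(ValueError):
        correlation_distance([1], [0])


def test_correlation_matrix_is_symmetric_and_bounded():
    rng = np.random.default_rng(2)
    X = rng.integers(0, 2, size=(10, 20))
    X[0] = 1  # a constant profile
    D = correlation_distance_matrix(pd.DataFrame(X))
    assert np.allclose(D, D.T)
    assert (D >= 0).all() and (D <= 2).all()
    assert (D[0, 1:] == MAX_CORRELATION_DISTANCE).all()
    assert np.allclose(np.diag(D), 0)


def test_build_profile_matrix_orders_by_panel_and_validates():
    panel = build_species_panel(50)
    presence = pd.DataFrame(
        np.ones((2, 50), dtype=int),
        index=["g1", "g2"],
        columns=list(panel["species"][::-1]),  # reversed order on purpose
    )
    m = build_profile_matrix(presence, panel)
    assert list(m.columns) == list(panel["species"])
    with pytest.raises(ValueError):
        build_profile_matrix(presence.rename(columns={"sp0001": "mystery"}), panel)


def test_profile_matrix_round_trips_through_tsv(tmp_path):
    cfg = SimulationConfig(n_genes=30, n_profile_species=40, module_specs=[],
                           profile_patterns=[(PRESENT_BROADLY, 10),
                                             (ABSENT_NONCILIATED, 10)],
                           profile_noise=0.1, seed=5)
    matrix, panel, _ = simulate_profiles(cfg)
    path = tmp_path / "profiles.tsv"
    io.write_binary_matrix(matrix, path)
    back = io.read_binary_matrix(path)
    pd.testing.assert_frame_equal(matrix, back, check_names=False)


def test_zero_noise_patterns_cluster_exactly_and_permutation_invariant():
    cfg = SimulationConfig(
        n_genes=90, n_profile_species=120, profile_noise=0.0, seed=9,
        module_specs=[],
        profile_patterns=[("PRESENT_BROADLY", 30), ("ABSENT_NONCILIATED", 30),
                          ("ABSENT_FOCAL_CLADE", 30)],
    )
    matrix, panel, gt = simulate_profiles(cfg)
    ca = cluster_profiles(matrix, min_cluster_size=10)

    def partition(assignment):
        groups = {}
        for g, lab in assignment.as_dict().items():
            groups.setdefault(lab, set()).add(g)
        return {frozenset(v) for v in groups.values()}

    truth = {}
    for g, pat in gt.pattern_of.items():
        truth.setdefault(pat, set()).add(g)
    assert partition(ca) == {frozenset(v) for v in truth.values()}

    rng = np.random.default_rng(0)
    perm = rng.permutation(len(matrix))
    ca_perm = cluster_profiles(matrix.iloc[perm], min_cluster_size=10)
    assert partition(ca_perm) == partition(ca)


def _panel_and_matrix(patterns):
    panel = build_species_panel(100)
    rows = {}
    from mcscreen.synthetic_data import _pattern_row
    for i, pat in enumerate(patterns):
        for k in range(6):
            rows[f"{pat}_{k}"] = _pattern_row(pat, panel)
    matrix = pd.DataFrame(rows).T
    matrix.columns = panel["species"]
    return panel, matrix


def test_annotate_focal_absent_and_broadly_present():
    panel, matrix = _panel_and_matrix([ABSENT_FOCAL_CLADE, PRESENT_BROADLY])
    from mcscreen.hierarchy import ClusterAssignment
    labels = [1] * 6 + [2] * 6
    ca = ClusterAssignment(items=list(matrix.index), labels=labels)
    ann = annotate_clusters(matrix, ca, panel)
    assert ABSENT_FOCAL_CLADE in ann.patterns[1]
    assert ann.patterns[2] == [PRESENT_BROADLY]
    assert ann.clade_fractions.loc[1, "focal"] == pytest.approx(0.0)
    assert ann.clade_fractions.loc[1, "non_focal_vertebrate"] == pytest.approx(1.0)
    frac = ann.clade_fractions
    assert ((frac >= 0) | frac.isna()).all().all()
    assert ((frac <= 1) | frac.isna()).all().all()


def test_annotate_non_ciliated_absence():
    panel, matrix = _panel_and_matrix([ABSENT_NONCILIATED])
    from mcscreen.hierarchy import ClusterAssignment
    ca = ClusterAssignment(items=list(matrix.index), labels=[1] * 6)
    ann = annotate_clusters(matrix, ca, panel)
    assert ABSENT_NONCILIATED in ann.patterns[1]
    assert ann.clade_fractions.loc[1, "non_ciliated"] == pytest.approx(0.0)
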