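"""Overexpression filter, identifier harmonization, binary matrix and
Jaccard distance properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from mcscreen.expression_screen import (
    ExperimentTable,
    build_binary_matrix,
    build_ortholog_lookup,
    cluster_signatures,
    drop_single_experiment_genes,
    filter_overexpressed,
    harmonize_ids,
    jaccard_distance,
    jaccard_distance_matrix,
)
from mcscreen.hierarchy import ClusterAssignment


def make_table(rows, exp="e1"):
    return ExperimentTable(
        experiment_id=exp,
        data=pd.DataFrame(rows, columns=["gene_id", "logfc", "pvalue"]),
    )


@pytest.mark.parametrize(
    "logfc,pvalue,kept",
    [
        (1.2, 0.01, True),   # clear overexpression
        (1.0, 0.05, True),   # both thresholds are inclusive
        (0.99, 0.001, False),  # below the fold-change threshold
        (2.0, 0.051, False),   # above the p threshold
    ],
)
def test_filter_threshold_boundaries(logfc, pvalue, kept):
    got = filter_overexpressed(make_table([("g", logfc, pvalue)]))
    assert (("g" in got) is kept)


def test_filter_missing_values_name_the_gene():
    with pytest.raises(ValueError, match="gBad"):
        filter_overexpressed(make_table([("gBad", np.nan, 0.01)]))


def test_filter_duplicate_rows_keep_smallest_pvalue():
    table = make_table([("g", 1.5, 0.2), ("g", 1.5, 0.01)])
    assert filter_overexpressed(table) == {"g"}


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    logfc=st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=30),
    thresholds=st.tuples(st.floats(0, 2), st.floats(0.001, 0.2)),
)
def test_filter_is_anti_monotone_in_thresholds(logfc, thresholds):
    """Raising logfc_min or lowering p_max never grows the gene set."""
    rng = np.random.default_rng(0)
    pvals = rng.uniform(0, 1, len(logfc))
    table = make_table(
        [(f"g{i}", lf, p) for i, (lf, p) in enumerate(zip(logfc, pvals))]
    )
    lf_min, p_max = thresholds
    loose = filter_overexpressed(table, lf_min, p_max)
    tighter_lf = filter_overexpressed(table, lf_min + 0.5, p_max)
    tighter_p = filter_overexpressed(table, lf_min, p_max / 2)
    assert tighter_lf <= loose
    assert tighter_p <= loose


def test_harmonize_one_to_one_and_identity():
    maps = {"mouse": build_ortholog_lookup(
        pd.DataFrame({"source_gene": ["Foxj1"], "target_gene": ["FOXJ1"]})
    )}
    got = harmonize_ids(
        {"e1": {"Foxj1"}, "e2": {"TP73"}},
        maps,
        {"e1": "mouse", "e2": "human"},
    )
    assert got == {"e1": {"FOXJ1"}, "e2": {"TP73"}}


def test_harmonize_union_semantics_for_co_orthologs():
    maps = {"xenopus": build_ortholog_lookup(
        pd.DataFrame({"source_gene": ["x1", "x1"], "target_gene": ["A", "B"]})
    )}
    got = harmonize_ids({"e1": {"x1"}}, maps, {"e1": "xenopus"})
    assert got["e1"] == {"A", "B"}


def test_harmonize_missing_map_names_experiment():
    with pytest.raises(ValueError, match="e9"):
        harmonize_ids({"e9": {"g"}}, {}, {"e9": "axolotl"})


def test_harmonize_drops_unmapped(caplog):
    maps = {"mouse": {"known": {"KNOWN"}}}
    got = harmonize_ids({"e1": {"known", "novel"}}, maps, {"e1": "mouse"})
    assert got["e1"] == {"KNOWN"}


def test_binary_matrix_layout():
    sets = {"e1": {"b", "a"}, "e2": set(), "e3": {"a"}, "e4": set()}
    m = build_binary_matrix(sets)
    assert list(m.columns) == ["e1", "e2", "e3", "e4"]
    assert list(m.index) == ["a", "b"]
    assert list(m.loc["a"]) == [1, 0, 1, 0]
    assert (m.sum(axis=1) >= 1).all()


def test_binary_matrix_requires_two_experiments_and_nonempty_union():
    with pytest.raises(ValueError):
        build_binary_matrix({"e1": {"a"}})
    with pytest.raises(ValueError):
        build_binary_matrix({"e1": set(), "e2": set()})


def test_jaccard_worked_example_and_identities():
    assert jaccard_distance([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(2 / 3)
    assert jaccard_distance([1, 0, 1], [1, 0, 1]) == 0.0
    assert jaccard_distance([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0
    with pytest.raises(ValueError):
        jaccard_distance([0, 0], [0, 0])


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.data())
def test_jaccard_is_a_metric_on_nonzero_binary_vectors(data):
    n = data.draw(st.integers(2, 12))
    vec = st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
        lambda v: any(v)
    )
    a, b, c = data.draw(vec), data.draw(vec), data.draw(vec)
    dab = jaccard_distance(a, b)
    dba = jaccard_distance(b, a)
    assert dab == dba
    assert 0.0 <= dab <= 1.0
    assert (dab == 0.0) == (a == b)
    assert dab <= jaccard_distance(a, c) + jaccard_distance(c, b) + 1e-12


def test_jaccard_matrix_agrees_with_scalar_and_scipy():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 2, size=(8, 6))
    X[X.sum(axis=1) == 0, 0] = 1
    m = pd.DataFrame(X)
    D = jaccard_distance_matrix(m)
    for i in range(8):
        for j in range(8):
            assert D[i, j] == pytest.approx(
                0.0 if i == j else jaccard_distance(X[i], X[j])
            )
    assert np.allclose(D, squareform(pdist(X.astype(bool), "jaccard")))


def _toy_clusters():
    # genes a,b in cluster 1 (multi-experiment); c,d in cluster 2 (single-exp)
    matrix = pd.DataFrame(
        {
            "e1": [1, 1, 1, 0, 1],
            "e2": [1, 1, 0, 1, 0],
            "e3": [0, 1, 0, 0, 0],
        },
        index=["a", "b", "c", "d", "x"],
    )
    clusters = ClusterAssignment(
        items=["a", "b", "c", "d", "x"], labels=[1, 1, 2, 2, 1]
    )
    return matrix, clusters


def test_drop_single_experiment_clusters_and_genes():
    matrix, clusters = _toy_clusters()
    retained, removed, removed_clusters = drop_single_experiment_genes(
        matrix, clusters
    )
    assert removed_clusters == [2]  # every member of cluster 2 has row-sum 1
    assert removed == {"c", "d", "x"}  # x removed by the row-sum rule alone
    assert retained == {"a", "b"}
    assert retained | removed == set(matrix.index)
    assert not retained & removed


def test_cluster_signature_fractions_and_sets():
    matrix, clusters = _toy_clusters()
    sig = cluster_signatures(matrix, clusters, signature_threshold=0.5)
    assert sig.fractions.loc[1, "e1"] == pytest.approx(1.0)
    assert ((sig.fractions >= 0) & (sig.fractions <= 1)).all().all()
    assert sig.signatures[1] == frozenset({"e1", "e2"})
    assert sig.signatures[2] == frozenset({"e1", "e2"})
    # identical signature sets are grouped (shared regulator semantics)
    assert sig.groups[("e1", "e2")] == [1, 2]


def test_fixture_planted_module_signature(bundle, fixture_matrix,
                                          fixture_clusters, fixture_signatures):
    """A module planted active in experiments {1, 9} yields that signature."""
    gt = bundle.ground_truth
    labels = fixture_clusters.as_dict()
    m3 = {g for g, mod in gt.module_of.items() if mod == "M3"}
    (cid,) = {labels[g] for g in m3}
    assert fixture_signatures.signatures[cid] == frozenset({"exp01", "exp09"})
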