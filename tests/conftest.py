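"""Shared fixtures: the deterministic paper-counts bundle and the pipeline
results derived from it (computed once per session)."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

from mcscreen.conservation import screen_proteome
from mcscreen.expression_screen import (
    build_binary_matrix,
    cluster_expression_profiles,
    cluster_signatures,
    drop_single_experiment_genes,
    filter_overexpressed,
)
from mcscreen.synthetic_data import fixture_paper_counts


@pytest.fixture(scope="session")
def bundle():
    return fixture_paper_counts()


@pytest.fixture(scope="session")
def fixture_matrix(bundle):
    sets = {t.experiment_id: filter_overexpressed(t) for t in bundle.de_tables}
    return build_binary_matrix(sets)


@pytest.fixture(scope="session")
def fixture_clusters(bundle, fixture_matrix):
    return cluster_expression_profiles(fixture_matrix)


@pytest.fixture(scope="session")
def fixture_retention(fixture_matrix, fixture_clusters):
    return drop_single_experiment_genes(fixture_matrix, fixture_clusters)


@pytest.fixture(scope="session")
def fixture_signatures(fixture_matrix, fixture_clusters):
    return cluster_signatures(fixture_matrix, fixture_clusters)


@pytest.fixture(scope="session")
def fixture_conservation(bundle):
    return screen_proteome(bundle.clade_table)
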