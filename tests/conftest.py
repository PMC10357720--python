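"""Shared fixtures: synthetic bundles at the canonical and a reduced scale."""

from __future__ import annotations

import pytest

from puvote.ensemble import LabelVector, build_label_vector
from puvote.io import GeneSetCollection
from puvote.simulate import SEED_SET_NAME, SimConfig, default_config, generate


def labels_from_bundle(bundle) -> LabelVector:
    positives = set(bundle.gene_sets[SEED_SET_NAME])
    exclusion = GeneSetCollection(
        sets={
            name: bundle.gene_sets[name]
            for name in bundle.gene_sets.names()
            if name.startswith("HALLMARK_") and name != SEED_SET_NAME
        }
    )
    first = next(iter(bundle.cohorts.values()))
    return build_label_vector(first.gene_ids, positives, exclusion)


@pytest.fixture(scope="session")
def bundle():
    """The canonical desk-scale synthetic study."""
    return generate(default_config())


@pytest.fixture(scope="session")
def labels(bundle):
    return labels_from_bundle(bundle)


SMALL_CONFIG = SimConfig(
    n_cohorts=2,
    genes_total=400,
    n_seed=20,
    n_hidden=12,
    n_excluded=40,
    patients_per_cohort=60,
    ppi_nodes=150,
    module_size=8,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for fast unit-level checks."""
    return generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_labels(small_bundle):
    return labels_from_bundle(small_bundle)
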