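"""Shared fixtures. Expensive pipeline runs are session-scoped so that the
acceptance tests and unit tests reuse one computation."""

from __future__ import annotations

import pytest

from kinfams import (
    ClassifyParams,
    FixtureConfig,
    classify_superfamily,
    generate_superfamily,
)
from kinfams.sequence_domains import build_functional_units, resolve_hits


def units_of(bundle, params: ClassifyParams | None = None):
    """Resolve a bundle's hits and build its functional units."""
    params = params or ClassifyParams()
    hits_by = {}
    for h in bundle.domain_hits:
        hits_by.setdefault(h.seq_id, []).append(h)
    units = []
    for s in bundle.sequences:
        arch = resolve_hits(hits_by.get(s.id, []), seq_id=s.id)
        units.extend(
            build_functional_units(
                arch,
                params.n_lobe_family,
                params.c_lobe_family,
                params.linker_max,
                sequence=s.residues,
            )
        )
    return units


def classify_bundle(bundle, params: ClassifyParams | None = None):
    params = params or ClassifyParams()
    return classify_superfamily(
        units_of(bundle, params), bundle.domain_hits, bundle.annotations, params
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic superfamily at seed 1."""
    return generate_superfamily(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """Classification of the default bundle."""
    return classify_bundle(default_bundle)


@pytest.fixture(scope="session")
def twenty_seed_runs():
    """(bundle, classification result) for seeds 0..19 of the default
    config; shared by the family-recovery and SDP-recovery acceptance
    tests."""
    runs = []
    for seed in range(20):
        bundle = generate_superfamily(FixtureConfig(seed=seed))
        runs.append((bundle, classify_bundle(bundle)))
    return runs
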