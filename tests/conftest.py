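"""Shared fixtures: small synthetic studies and hand-built alignments."""

from __future__ import annotations

import pytest

from phosphocons import (
    Msa,
    SimulationConfig,
    default_registry,
    simulate_study,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact end-to-end study: 4 archetypes x 8 proteins, full 100-species panel."""
    import dataclasses

    base = SimulationConfig()
    config = SimulationConfig(
        seed=20240,
        archetypes=tuple(
            dataclasses.replace(a, n_proteins=8) for a in base.archetypes
        ),
        validation_padding=300,
        null_terms=4,
        planted_terms_per_archetype=1,
        planted_term_size=6,
    )
    return simulate_study(config)


@pytest.fixture()
def toy_msa():
    """Reference ASPKY with one conserved, one S->T, one decayed species."""
    return Msa(
        {
            "REF": "ASPKY",
            "identical": "ASPKY",
            "st_swap": "ATPKY",
            "decayed": "AAPKF",
            "gappy": "A-PK-",
        },
        reference_id="REF",
    )
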