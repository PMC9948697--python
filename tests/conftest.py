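"""Shared fixtures: knowledge base, sim configs, domain/reference libraries.

Expensive seeded objects are session-scoped; all synthetic inputs are
generated programmatically (no stored fixtures).
"""

import pytest

from lipopeptidome import synthetic_data as sd
from lipopeptidome.knowledge_base import default_knowledge_base

SEED = 11


@pytest.fixture(scope="session")
def kb():
    return default_knowledge_base()


@pytest.fixture(scope="session")
def cfg0():
    """Zero-noise study conditions (planted architecture recovered exactly)."""
    return sd.SimConfig(seed=SEED, mutation_rate=0.0)


@pytest.fixture(scope="session")
def cfg05():
    """Default study conditions: 5% per-site divergence from the anchors."""
    return sd.SimConfig(seed=SEED, mutation_rate=0.05)


@pytest.fixture(scope="session")
def domain_lib(cfg05):
    """Domain-caller reference library (depends on seed only, not on rate)."""
    return sd.make_domain_library(cfg05)


@pytest.fixture(scope="session")
def refset05(cfg05):
    """Labelled specificity references at the default divergence."""
    return sd.make_reference_set(cfg05)


@pytest.fixture(scope="session")
def refsystems05(cfg05):
    """Per-family reference systems for homology scoring."""
    return sd.reference_systems(cfg05)
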