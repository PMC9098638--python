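import numpy as np
import pytest

from ordnet import (DiscretizationSpec, GroupDesign, TruePrecisionSpec,
                    build_precision, sample_ordinal)


@pytest.fixture(scope="session")
def chain_theta8():
    """8-node chain precision with every edge at partial correlation 0.3."""
    return build_precision(TruePrecisionSpec(structure="chain",
                                             partial_cor_value=0.3))


@pytest.fixture(scope="session")
def chain_names8():
    return TruePrecisionSpec().node_names


@pytest.fixture(scope="session")
def chain_dataset(chain_theta8, chain_names8):
    """Single-group ordinal sample (n = 2000) from the 8-node chain."""
    return sample_ordinal(chain_theta8, DiscretizationSpec(),
                          GroupDesign.single(2000), seed=42,
                          node_names=chain_names8)


def sample_single(theta, n, seed, n_categories=5, node_names=None):
    """Convenience wrapper used across test modules."""
    return sample_ordinal(theta, DiscretizationSpec(n_categories=n_categories),
                          GroupDesign.single(n), seed=seed,
                          node_names=node_names)
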