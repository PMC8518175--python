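import numpy as np
import pytest

from camtakit.synthetic import ExpressionSpec, SynthesisConfig, make_gene_family


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def family():
    """A ten-gene family at the study conditions: five paralog pairs on
    eight scaffolds, 12-13 exons per gene, 1 kb promoters."""
    return make_gene_family(SynthesisConfig(seed=11))


@pytest.fixture(scope="session")
def small_family():
    """A quicker family for I/O-oriented tests."""
    return make_gene_family(SynthesisConfig(seed=5, cds_codons=120))


def small_expression_spec(**overrides) -> ExpressionSpec:
    defaults = dict(n_hubs=1, n_partners_pos=8, n_partners_neg=8, n_noise=80)
    defaults.update(overrides)
    return ExpressionSpec(**defaults)
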