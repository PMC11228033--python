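import pytest

from cimpomics import CohortConfig, simulate_cohort

SMALL_KW = dict(
    n_genes=200,
    genome_length=2_000_000,
    n_regions={"meth": 260, "atac": 300, "h3k27ac": 160, "ctcf": 200},
    n_per_group={"CIMP": 6, "AML": 8, "T-ALL": 4, "HSPC": 2},
)


def small_config(seed=7, **overrides):
    kw = dict(SMALL_KW)
    kw.update(overrides)
    return CohortConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """Default small cohort with all planted effects on."""
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def null_cohort():
    """All effect parameters off: groups are exchangeable."""
    return simulate_cohort(
        small_config(seed=13, effect_log2fc=0.0, ctcf_coupling_beta=0.0,
                     meth_expr_rho=0.0)
    )
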