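import numpy as np
import pandas as pd
import pytest

import grnstates as g


@pytest.fixture(scope="session")
def small_cohort():
    """3 planted states x 60 cells, 10-gene regulons over 100 background genes."""
    spec = g.CohortSimSpec(
        n_states=3, cells_per_state=60, genes_per_regulon=10,
        n_background_genes=100, n_patients=6, regulon_effect=8.0, seed=11,
    )
    em, annot, regs, truth = g.simulate_cohort(spec)
    return {"spec": spec, "expr": em, "annot": annot, "regulons": regs, "truth": truth}


@pytest.fixture(scope="session")
def small_lognorm(small_cohort):
    return g.lognormalize(small_cohort["expr"])


@pytest.fixture(scope="session")
def small_activity(small_cohort, small_lognorm):
    return g.aucell_score(small_lognorm, small_cohort["regulons"],
                          top_fraction=0.05, tie_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_expr():
    """Deterministic 10-gene x 4-cell lognorm fixture with distinct values."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(0.1, 5.0, size=(10, 4))
    return g.ExpressionMatrix(vals, [f"g{i}" for i in range(10)],
                              [f"c{i}" for i in range(4)], layer="lognorm")
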