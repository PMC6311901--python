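import numpy as np
import pytest

import ribofeat as rf


@pytest.fixture(scope="session")
def cds_reference():
    return rf.generate_cds_reference(300, seed=11)


@pytest.fixture(scope="session")
def ref_tables(cds_reference):
    return rf.build_reference_tables(cds_reference, seed=12)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = rf.CohortConfig(
        n_ribo=25,
        n_noribo=25,
        seed=7,
        planted_effects={"fEgc": 0.1},
        repeat_insertion_probs={"LTR": (0.1, 0.4)},
    )
    return rf.generate_cohort(cfg)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])
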