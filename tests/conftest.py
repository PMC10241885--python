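import math

import numpy as np
import pytest

from snpscreen import GenotypeCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_tables(rng, n_tables, max_count=60):
    """Random valid count tables (both margins nonempty) as (m, 3) arrays."""
    case = rng.integers(0, max_count + 1, size=(n_tables, 3))
    control = rng.integers(0, max_count + 1, size=(n_tables, 3))
    # ensure nonempty margins
    empty = case.sum(axis=1) == 0
    case[empty, 0] = 1
    empty = control.sum(axis=1) == 0
    control[empty, 0] = 1
    return case, control


def table_from_rows(case_row, control_row) -> GenotypeCounts:
    return GenotypeCounts(*map(int, case_row), *map(int, control_row))


def expand_to_samples(counts: GenotypeCounts):
    """Per-sample genotype and phenotype vectors implied by a count table."""
    g, y = [], []
    for i, (ri, si) in enumerate(zip(counts.case(), counts.control())):
        g += [i] * int(ri) + [i] * int(si)
        y += [1] * int(ri) + [0] * int(si)
    return np.array(g, dtype=float), np.array(y, dtype=int)
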