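import numpy as np
import pytest
from hypothesis import settings

from ylineage.io import load_table1

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")
from ylineage.matrix import HaplotypeMatrix, SampleDef, SiteDef


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_sequenced(table1):
    return table1.sequenced_subset()


def make_matrix(rows: dict[str, str], populations: dict[str, str] | None = None,
                n_sites: int | None = None) -> HaplotypeMatrix:
    """Build a matrix from '0'/'1'/'?' strings keyed by sample id."""
    populations = populations or {}
    ids = list(rows)
    n_sites = n_sites or len(next(iter(rows.values())))
    sites = [SiteDef(locus_id=f"L{j:02d}", ancestral_allele="A",
                     derived_allele="G") for j in range(n_sites)]
    samples = [SampleDef(identifier=s, population=populations.get(s, ""))
               for s in ids]
    code = {"0": 0, "1": 1, "?": -1}
    calls = np.array([[code[c] for c in rows[s]] for s in ids], dtype=np.int8)
    return HaplotypeMatrix(sites, samples, calls)


@pytest.fixture
def tiny_matrix():
    return make_matrix({"a": "000", "b": "110", "c": "101"})
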