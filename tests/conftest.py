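import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from demeseed.core import GenotypeMatrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_matrix(calls, chroms=None, positions=None, loci=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a list of per-individual call rows."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    chroms = chroms if chroms is not None else ["I"] * n_sites
    positions = positions if positions is not None else list(range(1, n_sites + 1))
    loci = loci if loci is not None else [f"R{j}" for j in range(n_sites)]
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "rad_locus": loci, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(n_ind)], sites=sites, calls=calls
    )


@pytest.fixture
def small_layout():
    """12 sites spread over the six chromosomes (fast simulations)."""
    return {"I": 2, "II": 2, "III": 2, "IV": 2, "V": 2, "X": 2}
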