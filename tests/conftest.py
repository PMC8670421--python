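import numpy as np
import pandas as pd
import pytest

from stratiscope.io_model import CountMatrix
from stratiscope.synthetic_data import SyntheticConfig, generate_dataset


def make_count_matrix(counts, lengths=None, orf_prefix="orf", sample_prefix="s"):
    counts = np.asarray(counts)
    n, m = counts.shape
    orfs = [f"{orf_prefix}{i}" for i in range(n)]
    samples = [f"{sample_prefix}{j}" for j in range(m)]
    if lengths is None:
        lengths = np.full(n, 1000)
    return CountMatrix(
        pd.DataFrame(counts, index=orfs, columns=samples),
        pd.Series(np.asarray(lengths), index=orfs, name="length_bp"),
    )


def make_taxonomy(domains, rrna_flags=None, orf_prefix="orf", orders=None):
    n = len(domains)
    if rrna_flags is None:
        rrna_flags = [False] * n
    rows = []
    for i, (dom, rr) in enumerate(zip(domains, rrna_flags)):
        order = (orders[i] if orders else "unclassified") if dom != "unclassified" \
            else "unclassified"
        named = dom != "unclassified"
        rows.append(
            {
                "orf_id": f"{orf_prefix}{i}",
                "domain": dom,
                "phylum": "SomePhylum" if named else "unclassified",
                "class": "SomeClass" if named else "unclassified",
                "order": order if named else "unclassified",
                "family": "unclassified",
                "genus": "unclassified",
                "is_rrna_overlap": rr,
            }
        )
    df = pd.DataFrame(rows)
    return df.set_index("orf_id", drop=False)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared across tests."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A light config for tests that iterate over many seeds."""
    return SyntheticConfig(
        orfs_per_taxon=40, library_size_mean=5e4, seed=0,
        n_eukaryote_orfs=5, n_unclassified_orfs=3, n_rrna_overlap_orfs=2,
    )
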