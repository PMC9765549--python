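"""Shared fixtures: a small literature-style taxonomy and random-tree helpers."""

import numpy as np
import pytest

from synrecruit.taxonomy import build_taxonomy

# A miniature reference set shaped like the published strain tables: clade-I
# strains in subclades Ia/Ib, one strain each for clades II-IV, one SC 5.2
# and one SC 5.3 representative (no clade rank), and outgroup genomes.
STRAIN_RECORDS = [
    ("CC9311", "Ia", "I", "5.1", "Synechococcus", 2_606_748, False),
    ("ROS8604", "Ib", "I", "5.1", "Synechococcus", 2_500_000, False),
    ("M16.1", "IIa", "II", "5.1", "Synechococcus", 2_430_000, False),
    ("RS9915", "IIIa", "III", "5.1", "Synechococcus", 2_350_000, False),
    ("MVIR-16-1", "IVa", "IV", "5.1", "Synechococcus", 2_450_000, False),
    ("WH5701", None, None, "5.2", "Synechococcus", 2_860_000, False),
    ("RCC307", None, None, "5.3", "Synechococcus", 2_220_000, False),
    ("AQUA-OUT-1", None, None, None, None, 4_600_000, True),
    ("AQUA-OUT-2", None, None, None, None, 3_900_000, True),
]


@pytest.fixture(scope="session")
def strain_records():
    return list(STRAIN_RECORDS)


@pytest.fixture(scope="session")
def tree(strain_records):
    return build_taxonomy(strain_records)


def random_taxonomy_records(rng: np.random.Generator, n_clades=None,
                            strains_per_clade=None, n_outgroup=1):
    """Random strain records with valid rank structure."""
    n_clades = n_clades or int(rng.integers(2, 6))
    records = []
    for c in range(n_clades):
        clade = f"C{c}"
        n_strains = strains_per_clade or int(rng.integers(1, 4))
        for s in range(n_strains):
            subclade = f"C{c}{chr(ord('a') + s)}" if rng.random() < 0.8 else None
            records.append(
                (
                    f"C{c}S{s}", subclade, clade, "5.1", "Synechococcus",
                    int(rng.integers(2_000_000, 3_000_000)), False,
                )
            )
    for o in range(n_outgroup):
        records.append(
            (f"OG{o}", None, None, None, None,
             int(rng.integers(2_000_000, 6_000_000)), True)
        )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
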