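import numpy as np
import pytest

from savkit import build_snv_reachability, load_codon_table


@pytest.fixture(scope="session")
def codon_table():
    return load_codon_table()


@pytest.fixture(scope="session")
def reachability(codon_table):
    return build_snv_reachability(codon_table)


@pytest.fixture(scope="session")
def oracle_reachable_pairs(codon_table):
    """Brute-force SNV reachability: scan all 61x61 sense-codon pairs and
    collect amino-acid pairs whose codons differ at exactly one position."""
    sense = {c: aa for c, aa in codon_table.items() if aa != "*"}
    pairs = set()
    for ca, aa in sense.items():
        for cb, ab in sense.items():
            if aa == ab:
                continue
            if sum(x != y for x, y in zip(ca, cb)) == 1:
                pairs.add((aa, ab))
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(20170509)
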