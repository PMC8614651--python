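import numpy as np
import pytest
from hypothesis import settings

from cubscan.genetic_code import SENSE_CODONS, STOP_CODONS
from cubscan.seqio import CodingSequence
from cubscan.synthetic_data import generate_regime_panel

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_cds(codons, seq_id="s1", group="g"):
    """Build a CodingSequence directly from a codon list (ATG...stop)."""
    seq = "".join(codons)
    return CodingSequence(seq_id=seq_id, group=group, sequence=seq,
                          codons=tuple(codons))


@pytest.fixture(scope="session")
def four_group_panel():
    """A seeded four-group synthetic panel shared by the slower tests."""
    return generate_regime_panel(n_per_group=20, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_count_table(rng, max_count=20):
    """Random sense-codon count table (may contain zeros)."""
    from cubscan.cub_metrics import CodonCountTable
    counts = {c: int(rng.integers(0, max_count + 1)) for c in SENSE_CODONS}
    counts = {c: n for c, n in counts.items() if n > 0}
    return CodonCountTable.from_counts(counts)
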