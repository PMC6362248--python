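import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tssmine import synthetic_data as sd
from tssmine.sequence_io import reverse_complement

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model():
    """Packaged synthetic reference transposon (1638 nt, 227/1022/227)."""
    return sd.demo_model()


@pytest.fixture(scope="session")
def small_sim(model):
    """200-kb genome, 8 intact copies at 3% divergence, 2 ITR-less decoys."""
    params = sd.SimParams(seed=11, genome_length=200_000, n_copies=8, p_sub=0.03, n_decoys=2)
    records, truth = sd.generate_genome(model, params)
    return records, truth


@pytest.fixture(scope="session")
def clean_sim(model):
    """60-kb genome with 4 exact (undiverged) copies, mixed strands."""
    params = sd.SimParams(seed=5, genome_length=60_000, n_copies=4, p_sub=0.0)
    records, truth = sd.generate_genome(model, params)
    return records, truth


def sliding_window_oracle(records, query, min_identity=0.90):
    """Brute-force sliding-window alignment oracle (edit-distance based).

    Scans overlapping windows on both strands, computes the best infix
    alignment of the query in each window, and reports merged genomic
    intervals whose alignment identity reaches ``min_identity``.
    Independent of the package's seed-and-extend path.
    """
    import edlib

    qlen = len(query)
    step = max(1, qlen // 4)
    intervals = []
    for chrom, seq in records:
        for strand, q in (("+", query), ("-", reverse_complement(query))):
            for w0 in range(0, max(1, len(seq) - qlen + 1), step):
                window = seq[w0 : w0 + 2 * qlen]
                res = edlib.align(q, window, mode="HW", task="locations")
                if res["editDistance"] < 0:
                    continue
                identity = 1.0 - res["editDistance"] / qlen
                if identity >= min_identity:
                    loc = res["locations"][0]
                    intervals.append((chrom, w0 + loc[0], w0 + loc[1] + 1))
    # merge overlapping intervals per chromosome
    merged = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged


@pytest.fixture(scope="session")
def oracle():
    return sliding_window_oracle


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
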