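import numpy as np
import pandas as pd
import pytest

from regumine.genome import AnnotatedGenome
from regumine.motif import ALPHABET, Background, PFM, PWM, build_pfm, pfm_to_pwm
from regumine.synthetic import default_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic study at seed 1, shared across tests."""
    return default_scenario(seed=1)


@pytest.fixture
def toy_genome():
    """10 kb contig with one + strand gene at [1000, 1900)."""
    seq = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(10_000))
    genes = pd.DataFrame(
        [{"gene_id": "gA", "contig": "c1", "start": 1000, "end": 1900, "strand": "+"}]
    )
    return AnnotatedGenome(contigs={"c1": seq}, genes=genes)


def random_pwm(rng: np.random.Generator, length: int, gc: float = 0.5) -> PWM:
    """Random PFM from sampled sites, converted with a pseudocount."""
    sites = [
        "".join(ALPHABET[b] for b in rng.integers(0, 4, size=length))
        for _ in range(8)
    ]
    return pfm_to_pwm(build_pfm(sites), Background(gc), pseudocount=0.8)


def brute_force_scan(seq: str, pwm: PWM, floor: float):
    """Independent every-offset/strand scorer used as the scan oracle."""
    from regumine.genome import reverse_complement
    from regumine.motif import score_sequence

    length = pwm.length
    hits = []
    for start in range(len(seq) - length + 1):
        window = seq[start : start + length]
        s_fwd = score_sequence(pwm, window)
        if s_fwd >= floor:
            hits.append((start, "+", s_fwd))
        s_rev = score_sequence(pwm, reverse_complement(window))
        if s_rev >= floor:
            hits.append((start, "-", s_rev))
    return sorted(hits)


def brute_force_tail(
    pwm: PWM, background: Background, k: int, granularity: float | None = None
):
    """Exact score tail by enumerating all 4^k k-mers (k small).

    With ``granularity`` the per-position scores are floored to the grid first,
    matching the discretization convention of the dynamic-programming
    distribution, so floors can be compared exactly.
    """
    import itertools

    probs = background.base_probs
    matrix = pwm.scores
    if granularity is not None:
        matrix = np.floor(matrix / granularity) * granularity
    scores, weights = [], []
    for kmer in itertools.product(range(4), repeat=k):
        scores.append(float(sum(matrix[b, i] for i, b in enumerate(kmer))))
        weights.append(float(np.prod([probs[b] for b in kmer])))
    order = np.argsort(scores)
    return np.asarray(scores)[order], np.asarray(weights)[order]
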