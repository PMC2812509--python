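import numpy as np
import pytest

from rnai_rescue.synthetic_data import simulate_dataset


def brute_force_longest_stretch(ref: str, donor: str, breaks=frozenset()) -> int:
    """Independent quadratic oracle: try every substring, extend while the
    positions are identical A/C/G/T and no insertion break sits inside."""
    n = len(ref)
    best = 0
    for i in range(n):
        j = i
        while (
            j < n
            and ref[j] == donor[j]
            and ref[j] in "ACGT"
        ):
            j += 1
            if (j - 1) in breaks:
                break
        best = max(best, j - i)
    return best


def random_slice_pair(rng: np.random.Generator, n: int, match_prob: float):
    """Reference/donor pair with i.i.d. per-position identity."""
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    match = rng.random(n) < match_prob
    shift = rng.integers(1, 4, size=n)
    donor = np.where(match, ref, bases[(np.searchsorted(bases, ref) + shift) % 4])
    return "".join(ref), "".join(donor)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 20-gene five-species synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("synthetic")
    return simulate_dataset(outdir, n_genes=20, seed=7)
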