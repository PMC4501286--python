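import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epitopescan import AA_ALPHABET, ScoringMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_matrix(allele: str, seed: int, n: int = 9) -> ScoringMatrix:
    rng = np.random.default_rng(seed)
    return ScoringMatrix(allele=allele, values=rng.normal(size=(n, 20)), n=n)


def random_peptide(rng: np.random.Generator, n: int = 9) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def motif_matrices(motif: str, n_alleles: int, seed: int) -> dict[str, ScoringMatrix]:
    """Allele matrices in which the motif residue is strictly maximal at
    every position, so the motif is the unique top-scoring 9-mer.

    The motif cell sits just above the row's background maximum: the
    margin keeps the maximal-score guarantee while leaving peptides that
    merely share a few motif residues inside the background score range.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_alleles):
        vals = rng.uniform(0.0, 1.0, size=(9, 20))
        for p, aa in enumerate(motif):
            vals[p, AA_ALPHABET.index(aa)] = vals[p].max() + 0.1
        allele = f"DRB1_{i + 1:04d}"
        out[allele] = ScoringMatrix(allele=allele, values=vals)
    return out


@pytest.fixture
def toy_matrix() -> ScoringMatrix:
    return random_matrix("DRB1_0101", seed=11)
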