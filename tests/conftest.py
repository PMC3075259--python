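import numpy as np
import pytest

from netsnp.genotypes import MISSING, GenotypeMatrix


def matrix_from_calls(calls: dict[str, list[str]]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-SNP lists of 'A/G'-style calls."""
    snps = list(calls)
    n = len(next(iter(calls.values())))
    samples = [f"s{i}" for i in range(n)]
    dosage = np.full((len(snps), n), MISSING, dtype=np.int8)
    alleles = {}
    for i, rsid in enumerate(snps):
        parsed = []
        for c in calls[rsid]:
            parsed.append(None if c in ("./.", ".") else tuple(c.split("/")))
        observed = sorted({a for p in parsed if p for a in p})
        assert len(observed) <= 2, f"{rsid}: too many alleles in fixture"
        ref = observed[0] if observed else ""
        alt = observed[1] if len(observed) == 2 else ""
        alleles[rsid] = (ref, alt)
        for j, p in enumerate(parsed):
            if p is not None:
                dosage[i, j] = sum(1 for a in p if alt and a == alt)
    return GenotypeMatrix(samples, snps, dosage, alleles)


def matrix_from_dosage(dosage: np.ndarray, snps=None, confidence=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    snps = snps or [f"rs{i}" for i in range(dosage.shape[0])]
    samples = [f"s{j}" for j in range(dosage.shape[1])]
    alleles = {r: ("A", "G") for r in snps}
    return GenotypeMatrix(samples, snps, dosage, alleles, confidence)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
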